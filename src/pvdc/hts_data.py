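"""Chemical × assay potency matrices and assay annotations.

High-throughput screening pipelines report one potency per
(chemical, assay) pair — an AC50 (half-maximal activity concentration)
for dose–response assays or an LEC (lowest effective concentration) for
threshold readouts — with a sentinel of 1 M (``1e6`` µM) for chemicals
the assay called inactive.  This module provides the in-memory container
for such matrices, delimited-text I/O, and the hit filtering and
summarization used by every downstream scoring step.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel potency for inactive (chemical, assay) pairs: 1 M expressed in µM.
INACTIVE_UM: float = 1e6


class Direction(str, enum.Enum):
    """Direction of the assay readout relative to control."""

    UP = "up"
    DOWN = "down"
    UPDOWN = "updown"
    NA = "na"


class Measure(str, enum.Enum):
    """Kind of potency the assay reports."""

    AC50 = "AC50"
    LEC = "LEC"


def _norm_id(identifier: str) -> str:
    """Canonical match key: trimmed, case-folded."""
    return str(identifier).strip().casefold()


@dataclass(frozen=True)
class AssayAnnotation:
    """Metadata for one assay: platform, cell system, target mapping.

    ``target_feature`` names the vascular readout the assay contributes
    to (e.g. ``"CCL2_down"``, ``"PAI1_updown"``); empty when the assay
    does not participate in vascular scoring.
    """

    assay_id: str
    platform: str = ""
    cell_system: str = ""
    gene_symbol: str = ""
    target_feature: str = ""
    direction: Direction = Direction.NA
    measure: Measure = Measure.AC50


class AnnotationTable:
    """Collection of :class:`AssayAnnotation`, unique by assay id."""

    def __init__(self, annotations: Iterable[AssayAnnotation]):
        self._by_id: dict[str, AssayAnnotation] = {}
        for ann in annotations:
            key = _norm_id(ann.assay_id)
            if key in self._by_id:
                raise ValueError(f"duplicate assay_id: {ann.assay_id!r}")
            self._by_id[key] = ann

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self):
        return iter(self._by_id.values())

    def __contains__(self, assay_id: str) -> bool:
        return _norm_id(assay_id) in self._by_id

    def get(self, assay_id: str) -> AssayAnnotation | None:
        return self._by_id.get(_norm_id(assay_id))

    def assays_for_target(self, target_feature: str) -> list[str]:
        """Assay ids mapped to one target feature, in table order."""
        want = _norm_id(target_feature)
        return [
            a.assay_id for a in self._by_id.values()
            if _norm_id(a.target_feature) == want
        ]

    def target_features(self) -> list[str]:
        """Distinct nonempty target features, in first-seen order."""
        seen: dict[str, str] = {}
        for a in self._by_id.values():
            if a.target_feature and _norm_id(a.target_feature) not in seen:
                seen[_norm_id(a.target_feature)] = a.target_feature
        return list(seen.values())

    def genes_for_assays(self, assay_ids: Iterable[str]) -> dict[str, str]:
        """Map assay id → gene symbol for the given assays (empty skipped)."""
        out = {}
        for aid in assay_ids:
            ann = self.get(aid)
            if ann is not None and ann.gene_symbol:
                out[aid] = ann.gene_symbol
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AnnotationTable":
        cols = {c.strip().lower(): c for c in df.columns}
        if "assay_id" not in cols:
            raise ValueError("annotation table needs an 'assay_id' column")

        def cell(row, name, default=""):
            if name not in cols:
                return default
            v = row[cols[name]]
            return "" if pd.isna(v) else str(v).strip()

        anns = []
        for _, row in df.iterrows():
            anns.append(
                AssayAnnotation(
                    assay_id=cell(row, "assay_id"),
                    platform=cell(row, "platform"),
                    cell_system=cell(row, "cell_system"),
                    gene_symbol=cell(row, "gene_symbol"),
                    target_feature=cell(row, "target_feature"),
                    direction=Direction(cell(row, "direction", "na") or "na"),
                    measure=Measure(cell(row, "measure", "AC50") or "AC50"),
                )
            )
        return cls(anns)


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read an assay annotation table from delimited text (csv/tsv)."""
    return AnnotationTable.from_frame(pd.read_csv(path, sep=_sep_for(path)))


class PotencyMatrix:
    """Chemicals × assays micromolar potency matrix.

    Values are strictly positive and at most ``1e6`` µM; inactive pairs
    are stored as exactly ``1e6`` µM.  Chemical and assay identifiers
    keep their original spelling but match case-insensitively after
    whitespace trimming.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        provenance: str = "",
    ):
        vals = values.astype(float)
        arr = vals.to_numpy()
        if arr.size:
            bad = ~np.isfinite(arr) | (arr <= 0) | (arr > INACTIVE_UM)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    "potency out of range (must be in (0, 1e6] µM) at "
                    f"chemical {vals.index[i]!r}, assay {vals.columns[j]!r}: "
                    f"{arr[i, j]!r}"
                )
        keys = [_norm_id(c) for c in vals.index]
        if len(set(keys)) != len(keys):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise ValueError(f"duplicate chemical id (case-insensitive): {dup!r}")
        akeys = [_norm_id(a) for a in vals.columns]
        if len(set(akeys)) != len(akeys):
            dup = next(k for k in akeys if akeys.count(k) > 1)
            raise ValueError(f"duplicate assay id (case-insensitive): {dup!r}")
        self._df = vals
        self._chem_key = dict(zip(keys, vals.index))
        self._assay_key = dict(zip(akeys, vals.columns))
        self.provenance = provenance

    # -- basic accessors ------------------------------------------------
    @property
    def chemicals(self) -> list[str]:
        return list(self._df.index)

    @property
    def assays(self) -> list[str]:
        return list(self._df.columns)

    @property
    def values(self) -> pd.DataFrame:
        """The underlying potency table (copy-safe view)."""
        return self._df

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def row(self, chemical: str) -> pd.Series:
        """Potency row for one chemical (case-insensitive lookup)."""
        key = _norm_id(chemical)
        if key not in self._chem_key:
            raise KeyError(f"unknown chemical: {chemical!r}")
        return self._df.loc[self._chem_key[key]]

    def is_hit(self) -> pd.DataFrame:
        """Boolean mask of non-sentinel (active) cells."""
        return self._df < INACTIVE_UM

    # -- I/O ------------------------------------------------------------
    def write(self, path: str | Path) -> None:
        """Write as delimited text; sentinel cells serialize as blanks."""
        out = self._df.where(self._df < INACTIVE_UM)
        out.to_csv(path, sep=_sep_for(path), index_label="chemical")

    @classmethod
    def from_records(
        cls,
        chemicals: Sequence[str],
        assays: Sequence[str],
        hits: Mapping[tuple[str, str], float] | None = None,
        provenance: str = "",
    ) -> "PotencyMatrix":
        """Build an all-inactive matrix, then fill the given hit cells."""
        df = pd.DataFrame(
            INACTIVE_UM, index=list(chemicals), columns=list(assays), dtype=float
        )
        for (chem, assay), val in (hits or {}).items():
            df.loc[chem, assay] = val
        return cls(df, provenance=provenance)


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt", ".tab")) else ","


def read_potency_matrix(
    path: str | Path,
    annotations: AnnotationTable | None = None,
    unit: str = "uM",
) -> PotencyMatrix:
    """Read a chemical × assay potency matrix from delimited text.

    Layout: header row of assay ids, first column the chemical id, one
    row per chemical.  Blank cells mean inactive and are mapped to the
    1e6 µM sentinel.  ``unit="M"`` declares molar input, converted to µM
    at read time.  Nonpositive or nonnumeric cells and duplicate
    chemical ids are rejected with their location.
    """
    if unit not in ("uM", "M"):
        raise ValueError(f"unit must be 'uM' or 'M', got {unit!r}")
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: no columns found")
    chem_col = df.columns[0]
    chemicals = [c.strip() for c in df[chem_col]]
    keys = [_norm_id(c) for c in chemicals]
    seen: set[str] = set()
    for i, k in enumerate(keys):
        if k in seen:
            raise ValueError(
                f"{path}: duplicate chemical id {chemicals[i]!r} (row {i + 2})"
            )
        seen.add(k)
    assay_cols = list(df.columns[1:])
    scale = 1e6 if unit == "M" else 1.0
    data = np.full((len(chemicals), len(assay_cols)), INACTIVE_UM)
    for j, col in enumerate(assay_cols):
        for i, raw in enumerate(df[col]):
            cell = str(raw).strip()
            if cell == "" or cell.lower() in ("na", "nan"):
                continue
            try:
                val = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: nonnumeric potency {cell!r} at chemical "
                    f"{chemicals[i]!r}, assay {col!r}"
                ) from None
            if not math.isfinite(val) or val <= 0:
                raise ValueError(
                    f"{path}: nonpositive potency {cell!r} at chemical "
                    f"{chemicals[i]!r}, assay {col!r}"
                )
            data[i, j] = min(val * scale, INACTIVE_UM)
    mat = pd.DataFrame(
        data, index=chemicals, columns=[a.strip() for a in assay_cols]
    )
    if annotations is not None:
        missing = [a for a in mat.columns if a not in annotations]
        if missing:
            raise ValueError(
                f"{path}: assays absent from annotation table: {missing}"
            )
    return PotencyMatrix(mat, provenance=str(path))


@dataclass
class HitSummary:
    """Aggregate view of the active cells of a potency matrix.

    ``mean_potency`` is the arithmetic mean of hit values in µM and is
    ``None`` when there are no hits.  ``n_at_or_below`` counts hit
    values ≤ the stated cutoff (inclusive).
    """

    n_hits: int
    mean_potency: float | None
    threshold: float
    n_at_or_below: int
    per_chemical_hits: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_hits != sum(self.per_chemical_hits.values()):
            raise ValueError("n_hits inconsistent with per_chemical_hits")
        if not 0 <= self.n_at_or_below <= self.n_hits:
            raise ValueError("n_at_or_below out of [0, n_hits]")


def filter_hits(m: PotencyMatrix, threshold: float) -> HitSummary:
    """Summarize hits: count, mean potency, count at or below threshold.

    A (chemical, assay) pair is a hit iff its value is below the
    inactive sentinel; the sentinel never enters means or counts.
    """
    if not (0 < threshold <= INACTIVE_UM):
        raise ValueError(f"threshold must be in (0, 1e6] µM, got {threshold!r}")
    mask = m.is_hit()
    vals = m.values.to_numpy()[mask.to_numpy()]
    per_chem = {c: int(n) for c, n in mask.sum(axis=1).items()}
    return HitSummary(
        n_hits=int(vals.size),
        mean_potency=float(vals.mean()) if vals.size else None,
        threshold=float(threshold),
        n_at_or_below=int((vals <= threshold).sum()),
        per_chemical_hits=per_chem,
    )


def chemicals_with_min_hits(m: PotencyMatrix, k: int) -> list[str]:
    """Chemicals with at least ``k`` active assays, in input order."""
    if k < 1:
        raise ValueError(f"k must be ≥ 1, got {k!r}")
    counts = m.is_hit().sum(axis=1)
    return [c for c in m.chemicals if counts[c] >= k]
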