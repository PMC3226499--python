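"""Chemical–pathway perturbation scores.

A pathway perturbation score aggregates a chemical's assay hits at the
pathway level: it is the minimum potency (µM) over all hits on assays
whose gene symbols belong to the pathway, and it is defined only when
the chemical is active against at least ``min_targets`` distinct genes
in the pathway (default 5).  "Active" covers both AC50- and
LEC-measured hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .hts_data import INACTIVE_UM, AnnotationTable, PotencyMatrix, _norm_id

logger = logging.getLogger(__name__)

#: Minimum number of distinct active pathway genes for a defined score.
DEFAULT_MIN_TARGETS = 5


@dataclass(frozen=True)
class PathwayMap:
    """A named gene set with its annotation source (GO, KEGG, IPA...)."""

    pathway_id: str
    genes: tuple[str, ...]
    source: str = ""
    description: str = ""

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"pathway {self.pathway_id!r}: empty gene set")
        keys = [_norm_id(g) for g in self.genes]
        if len(set(keys)) != len(keys):
            raise ValueError(
                f"pathway {self.pathway_id!r}: duplicate genes in set"
            )

    def __contains__(self, gene: str) -> bool:
        return _norm_id(gene) in {_norm_id(g) for g in self.genes}


@dataclass
class PathwayScore:
    """Score for one (chemical, pathway) pair.

    ``score`` is µM, or ``None`` (undefined) when fewer than
    ``min_targets`` distinct pathway genes were hit.
    """

    chemical: str
    pathway_id: str
    score: float | None
    n_active_targets: int

    def __post_init__(self):
        if self.score is not None and self.score >= INACTIVE_UM:
            raise ValueError("defined score must be below the inactive sentinel")


def read_gmt(path: str | Path) -> list[PathwayMap]:
    """Read gene sets in GMT format: id TAB description TAB genes...

    A description of the form ``"source:text"`` (e.g. ``"GO:Process
    fibrinolysis"``) sets the pathway's source tag to the prefix.
    """
    pathways = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line needs id, description, ≥1 gene"
            )
        pid, desc, *genes = parts
        genes = [g.strip() for g in genes if g.strip()]
        source = desc.split(":", 1)[0] if ":" in desc else ""
        pathways.append(
            PathwayMap(
                pathway_id=pid.strip(),
                genes=tuple(dict.fromkeys(genes)),
                source=source,
                description=desc.strip(),
            )
        )
    return pathways


def perturbation_score(
    row: pd.Series,
    annotations: AnnotationTable,
    pmap: PathwayMap,
    min_targets: int = DEFAULT_MIN_TARGETS,
    chemical: str | None = None,
) -> PathwayScore:
    """Score one chemical against one pathway.

    ``n_active_targets`` counts distinct gene symbols in the pathway
    with at least one hit; when it reaches ``min_targets`` the score is
    the minimum potency over all hits on pathway-mapped assays,
    otherwise the score is undefined.  A pathway with no mapped assays
    yields an undefined score with zero active targets (not an error).
    """
    if min_targets < 1:
        raise ValueError(f"min_targets must be ≥ 1, got {min_targets!r}")
    pathway_genes = {_norm_id(g) for g in pmap.genes}
    active_genes: set[str] = set()
    hit_potencies: list[float] = []
    for assay in row.index:
        ann = annotations.get(assay)
        if ann is None or not ann.gene_symbol:
            continue
        if _norm_id(ann.gene_symbol) not in pathway_genes:
            continue
        value = float(row[assay])
        if value < INACTIVE_UM:
            active_genes.add(_norm_id(ann.gene_symbol))
            hit_potencies.append(value)
    n_active = len(active_genes)
    score = min(hit_potencies) if n_active >= min_targets else None
    return PathwayScore(
        chemical=chemical if chemical is not None else str(row.name),
        pathway_id=pmap.pathway_id,
        score=score,
        n_active_targets=n_active,
    )


def score_all(
    m: PotencyMatrix,
    annotations: AnnotationTable,
    pathways: Sequence[PathwayMap],
    min_targets: int = DEFAULT_MIN_TARGETS,
) -> pd.DataFrame:
    """Score every (chemical, pathway) pair.

    Returns one row per pair with columns ``chemical``, ``pathway_id``,
    ``source``, ``score`` (NaN when undefined — serialized as an empty
    cell), and ``n_active_targets``.  Annotated genes absent from every
    pathway are logged, never fatal.
    """
    covered = {_norm_id(g) for p in pathways for g in p.genes}
    orphans = sorted(
        {
            ann.gene_symbol
            for ann in annotations
            if ann.gene_symbol and _norm_id(ann.gene_symbol) not in covered
        }
    )
    if orphans:
        logger.info(
            "annotated genes absent from all pathways: %s", ", ".join(orphans)
        )
    rows = []
    for chem in m.chemicals:
        row = m.row(chem)
        for pmap in pathways:
            ps = perturbation_score(
                row, annotations, pmap, min_targets=min_targets, chemical=chem
            )
            rows.append(
                {
                    "chemical": ps.chemical,
                    "pathway_id": ps.pathway_id,
                    "source": pmap.source,
                    "score": ps.score,
                    "n_active_targets": ps.n_active_targets,
                }
            )
    return pd.DataFrame(
        rows, columns=["chemical", "pathway_id", "source", "score", "n_active_targets"]
    )


def pathway_feature_matrix(
    scores: pd.DataFrame,
    c_inactive: float = INACTIVE_UM,
    c_floor: float = 1e-3,
) -> pd.DataFrame:
    """Pivot pathway scores into a chemicals × pathways unit-scale matrix.

    Defined scores are transformed with the same clipped log10 ratio
    used for assay potencies; undefined scores enter as 0 (no
    perturbation evidence), keeping downstream discriminant fits free of
    missing values.
    """
    from .vbs import VBSConfig, assay_unit_score

    cfg = VBSConfig(
        targets=("x",), weights=(1.0,), c_inactive=c_inactive, c_floor=c_floor
    )
    wide = scores.pivot(index="chemical", columns="pathway_id", values="score")
    return wide.map(
        lambda v: 0.0 if pd.isna(v) else assay_unit_score(float(v), cfg)
    )
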