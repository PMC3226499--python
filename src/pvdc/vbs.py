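"""Vascular bioactivity score (VBS) and ToxPi profiles.

A chemical's VBS is a weighted sum, over a small ordered set of vascular
target features, of unit scores derived from the log-transformed
potencies of the assays mapped to each target.  Chemicals scoring above
the library mean are flagged as putative vascular disruptor compounds
(pVDCs).  ToxPi (Toxicological Priority Index) profiles render the same
per-target evidence as radial charts: slice angle proportional to the
target's weight, slice radius the target score normalized to the most
active chemical in the set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .hts_data import INACTIVE_UM, AnnotationTable, PotencyMatrix

#: The six vascular target features, in order of descending influence.
DEFAULT_TARGETS: tuple[str, ...] = (
    "VEGFR2_down",
    "TIE2_inhib",
    "CCL2_down",
    "PAI1_updown",
    "CXCL10_up",
    "uPAR_updown",
)

#: Default weights, non-increasing along DEFAULT_TARGETS.
DEFAULT_WEIGHTS: tuple[float, ...] = (6.0, 5.0, 4.0, 3.0, 2.0, 1.0)


@dataclass(frozen=True)
class VBSConfig:
    """Targets, weights and potency normalization for VBS.

    ``weights`` must be strictly positive and non-increasing in target
    order (targets are listed in descending influence).  ``c_inactive``
    is the inactive sentinel (µM); ``c_floor`` the potency at which the
    unit score saturates at 1.  ``aggregation`` combines a target's
    assay scores: ``"max"`` takes the most potent assay, ``"mean"``
    averages.
    """

    targets: tuple[str, ...] = DEFAULT_TARGETS
    weights: tuple[float, ...] = DEFAULT_WEIGHTS
    c_inactive: float = INACTIVE_UM
    c_floor: float = 1e-3
    aggregation: str = "max"

    def __post_init__(self):
        if len(self.targets) != len(self.weights):
            raise ValueError("targets and weights must align")
        if not self.targets:
            raise ValueError("at least one target required")
        if any(w <= 0 for w in self.weights):
            raise ValueError("weights must be strictly positive")
        if any(a < b for a, b in zip(self.weights, self.weights[1:])):
            raise ValueError("weights must be non-increasing in target order")
        if not 0 < self.c_floor < self.c_inactive:
            raise ValueError("require 0 < c_floor < c_inactive")
        if self.aggregation not in ("max", "mean"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "VBSConfig":
        """Load a flat key–value config (targets, weights, floors)."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "targets" in raw:
            kwargs["targets"] = tuple(str(t) for t in raw["targets"])
        if "weights" in raw:
            kwargs["weights"] = tuple(float(w) for w in raw["weights"])
        for key in ("c_inactive", "c_floor"):
            if key in raw:
                kwargs[key] = float(raw[key])
        if "aggregation" in raw:
            kwargs["aggregation"] = str(raw["aggregation"])
        return cls(**kwargs)


def assay_unit_score(potency: float, cfg: VBSConfig = VBSConfig()) -> float:
    """Map a µM potency onto [0, 1] via a clipped log10 ratio.

    score = clip(log10(c_inactive / potency) / log10(c_inactive / c_floor), 0, 1)

    The inactive sentinel maps to 0; potencies at or below ``c_floor``
    saturate at 1; more potent (smaller) values never score lower.
    """
    if not (isinstance(potency, (int, float)) and math.isfinite(potency)):
        raise ValueError(f"potency must be a finite number, got {potency!r}")
    if potency <= 0:
        raise ValueError(f"potency must be > 0 µM, got {potency!r}")
    span = math.log10(cfg.c_inactive / cfg.c_floor)
    score = math.log10(cfg.c_inactive / potency) / span
    return min(max(score, 0.0), 1.0)


@dataclass
class VBSResult:
    """Per-chemical target scores and composite VBS."""

    chemical: str
    target_scores: dict[str, float]
    vbs: float
    is_pvdc: bool | None = None
    rank: int | None = None


def _target_assay_map(
    annotations: AnnotationTable, cfg: VBSConfig
) -> dict[str, list[str]]:
    mapping = {t: annotations.assays_for_target(t) for t in cfg.targets}
    missing = [t for t, assays in mapping.items() if not assays]
    if missing:
        raise ValueError(f"targets with no mapped assay: {missing}")
    return mapping


def vbs_result(
    row: pd.Series,
    annotations: AnnotationTable,
    cfg: VBSConfig = VBSConfig(),
    chemical: str | None = None,
) -> VBSResult:
    """Score one chemical's potency row.

    Each target's score aggregates (max or mean) the unit scores of its
    mapped assays; the VBS is the weight-dot-score sum.  Deterministic.
    """
    mapping = _target_assay_map(annotations, cfg)
    scores: dict[str, float] = {}
    for target, assays in mapping.items():
        unit = [assay_unit_score(float(row[a]), cfg) for a in assays]
        scores[target] = max(unit) if cfg.aggregation == "max" else float(
            np.mean(unit)
        )
    total = float(
        sum(w * scores[t] for t, w in zip(cfg.targets, cfg.weights))
    )
    name = chemical if chemical is not None else str(row.name)
    return VBSResult(chemical=name, target_scores=scores, vbs=total)


def score_matrix(
    m: PotencyMatrix,
    annotations: AnnotationTable,
    cfg: VBSConfig = VBSConfig(),
    cutoff: float | None = None,
) -> pd.DataFrame:
    """Score every chemical; classify pVDCs; rank by VBS descending.

    Returns a frame indexed by chemical with one column per target unit
    score plus ``vbs``, ``is_pvdc`` and ``rank`` (1-based; ties broken
    alphabetically by chemical id).
    """
    results = [
        vbs_result(m.row(c), annotations, cfg, chemical=c) for c in m.chemicals
    ]
    df = pd.DataFrame(
        {t: [r.target_scores[t] for r in results] for t in cfg.targets},
        index=[r.chemical for r in results],
    )
    df["vbs"] = [r.vbs for r in results]
    df["is_pvdc"] = classify_pvdc(df["vbs"], cutoff=cutoff)
    order = sorted(df.index, key=lambda c: (-df.at[c, "vbs"], c.casefold()))
    df["rank"] = pd.Series(
        {c: i + 1 for i, c in enumerate(order)}, dtype=int
    )
    df.index.name = "chemical"
    return df


def classify_pvdc(
    vbs_scores: Sequence[float] | pd.Series,
    cutoff: float | None = None,
) -> pd.Series | np.ndarray:
    """Flag chemicals at or above the cutoff as pVDCs.

    The default cutoff is the arithmetic mean of all scores — the
    above-mean rule used to call 123 of 309 library chemicals.  The
    comparison is inclusive (``vbs >= cutoff``).
    """
    arr = np.asarray(vbs_scores, dtype=float)
    if arr.size == 0 and cutoff is None:
        raise ValueError("empty score list requires an explicit cutoff")
    if cutoff is None:
        cutoff = float(arr.mean())
    flags = arr >= cutoff
    if isinstance(vbs_scores, pd.Series):
        return pd.Series(flags, index=vbs_scores.index)
    return flags


def assay_feature_matrix(
    m: PotencyMatrix, cfg: VBSConfig = VBSConfig()
) -> pd.DataFrame:
    """Chemicals × assays matrix of unit scores in [0, 1].

    Applies :func:`assay_unit_score` cellwise; inactive sentinels map to
    0.  This is the assay-level feature block fed to discriminant
    signature fitting.
    """
    span = math.log10(cfg.c_inactive / cfg.c_floor)
    arr = m.values.to_numpy(dtype=float)
    scores = np.clip(np.log10(cfg.c_inactive / arr) / span, 0.0, 1.0)
    return pd.DataFrame(scores, index=m.chemicals, columns=m.assays)


@dataclass
class ToxPiProfile:
    """One chemical's radial profile: per-target (value, angular share)."""

    chemical: str
    slices: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def values(self) -> list[float]:
        return [v for v, _ in self.slices.values()]

    @property
    def fractions(self) -> list[float]:
        return [f for _, f in self.slices.values()]


def toxpi_profiles(
    scores: pd.DataFrame,
    cfg: VBSConfig = VBSConfig(),
) -> list[ToxPiProfile]:
    """Normalize target scores into ToxPi slices, ranked by VBS.

    Slice value = target score divided by the per-target maximum over
    all chemicals (zero when the whole slice is zero); angular fraction
    = weight / total weight.  Profiles are returned in VBS-descending
    order with alphabetical tie-break.
    """
    if scores.empty:
        raise ValueError("at least one chemical required")
    wsum = float(sum(cfg.weights))
    fractions = {t: w / wsum for t, w in zip(cfg.targets, cfg.weights)}
    maxima = {t: float(scores[t].max()) for t in cfg.targets}
    order = sorted(
        scores.index, key=lambda c: (-float(scores.at[c, "vbs"]), str(c).casefold())
    )
    profiles = []
    for chem in order:
        slices = {}
        for t in cfg.targets:
            raw = float(scores.at[chem, t])
            value = raw / maxima[t] if maxima[t] > 0 else 0.0
            slices[t] = (value, fractions[t])
        profiles.append(ToxPiProfile(chemical=str(chem), slices=slices))
    return profiles


def render_toxpi(
    profiles: Iterable[ToxPiProfile],
    out_dir: str | Path,
    top: int | None = None,
    grid_name: str = "toxpi_grid.png",
) -> list[Path]:
    """Draw one radial chart per chemical plus a top-N grid sheet.

    Slice angle is proportional to the target weight and radius to the
    normalized slice value.  Returns the written file paths; rejects an
    unwritable output directory.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib import cm

    profiles = list(profiles)
    if not profiles:
        raise ValueError("at least one profile required")
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ValueError(f"unwritable output path {out}: {exc}") from exc
    if top is not None:
        profiles = profiles[:top]

    colors = cm.tab10.colors

    def _draw(ax, profile: ToxPiProfile) -> None:
        theta = 0.0
        for i, (target, (value, frac)) in enumerate(profile.slices.items()):
            width = 2 * math.pi * frac
            ax.bar(
                x=theta + width / 2,
                height=value,
                width=width,
                bottom=0.0,
                color=colors[i % len(colors)],
                edgecolor="white",
                linewidth=0.5,
                label=target,
            )
            theta += width
        ax.set_ylim(0, 1)
        ax.set_xticks([])
        ax.set_yticks([])
        ax.set_title(profile.chemical, fontsize=7)

    written: list[Path] = []
    for profile in profiles:
        fig, ax = plt.subplots(
            figsize=(2.2, 2.2), subplot_kw={"projection": "polar"}
        )
        _draw(ax, profile)
        safe = "".join(
            ch if ch.isalnum() or ch in "-_." else "_" for ch in profile.chemical
        )
        path = out / f"toxpi_{safe}.png"
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    ncol = min(10, max(1, math.ceil(math.sqrt(len(profiles)))))
    nrow = math.ceil(len(profiles) / ncol)
    fig, axes = plt.subplots(
        nrow,
        ncol,
        figsize=(1.6 * ncol, 1.8 * nrow),
        subplot_kw={"projection": "polar"},
    )
    axes = np.atleast_1d(axes).ravel()
    for ax in axes[len(profiles):]:
        ax.set_visible(False)
    for ax, profile in zip(axes, profiles):
        _draw(ax, profile)
    grid_path = out / grid_name
    fig.savefig(grid_path, dpi=100, bbox_inches="tight")
    plt.close(fig)
    written.append(grid_path)
    return written
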