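"""Synthetic HTS screens with planted vascular-disruptor structure.

The generator emulates a phase-I-like screening campaign — a few
hundred chemicals against a hundred-plus assays with sparse hits and
log-spread micromolar potencies — in which a planted subset of "active"
chemicals perturbs the six vascular target features.  Each active
belongs to one of two mechanism groups: PAS-linked chemicals
preferentially hit the plasminogen-activating-system readouts
(PAI-1, uPAR) and produce rabbit fetal-loss endpoints, while
chemokine-linked chemicals hit CCL2/CXCL10 and produce rat skeletal
endpoints.  Every stage of the analysis can therefore be scored against
known ground truth: which chemicals are active, which features carry
their mechanism, and which species labels they should receive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .hts_data import (
    INACTIVE_UM,
    AnnotationTable,
    AssayAnnotation,
    Direction,
    Measure,
    PotencyMatrix,
)
from .pathways import PathwayMap
from .toxref import EndpointRecord
from .vbs import DEFAULT_TARGETS

#: Gene symbol behind each vascular target feature.
TARGET_GENES: dict[str, str] = {
    "VEGFR2_down": "KDR",
    "TIE2_inhib": "TEK",
    "CCL2_down": "CCL2",
    "PAI1_updown": "SERPINE1",
    "CXCL10_up": "CXCL10",
    "uPAR_updown": "PLAUR",
}

#: Mechanism groups: the shared vascular core hit by every active, and
#: the group-specific target pairs.
CORE_TARGETS = ("VEGFR2_down", "TIE2_inhib")
PAS_TARGETS = ("PAI1_updown", "uPAR_updown")
CHEMOKINE_TARGETS = ("CCL2_down", "CXCL10_up")

MECHANISM_TARGETS = {"PAS": PAS_TARGETS, "chemokine": CHEMOKINE_TARGETS}
MECHANISM_SPECIES = {"PAS": "rabbit", "chemokine": "rat"}
MECHANISM_CATEGORIES = {
    "PAS": ("maternal pregnancy loss", "embryo fetal loss"),
    "chemokine": ("skeletal: axial", "skeletal: appendicular"),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters for the synthetic screen.

    Defaults mirror a phase-I-like campaign: 309 chemicals, 120 assays,
    ~40% of the library planted active, hit potencies log10-uniform on
    [0.1, 50] µM, a 2% background false-hit rate, and an endpoint model
    in which PAS-linked actives produce rabbit fetal-loss records with
    probability 0.85 and chemokine-linked actives produce rat skeletal
    records with probability 0.8, corrupted by 5% cross-species label
    noise.
    """

    n_chemicals: int = 309
    n_assays: int = 120
    targets: tuple[str, ...] = DEFAULT_TARGETS
    assays_per_target: int = 2
    active_fraction: float = 0.4
    potency_low: float = 0.1
    potency_high: float = 50.0
    background_hit_rate: float = 0.02
    p_core: float = 0.8
    p_own_mechanism: float = 0.9
    p_other_mechanism: float = 0.1
    p_endpoint_pas: float = 0.85
    p_endpoint_chemokine: float = 0.8
    label_noise: float = 0.05
    min_target_features: int = 3
    seed: int = 0

    def __post_init__(self):
        for name in (
            "active_fraction",
            "background_hit_rate",
            "p_core",
            "p_own_mechanism",
            "p_other_mechanism",
            "p_endpoint_pas",
            "p_endpoint_chemokine",
            "label_noise",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if not 0 < self.potency_low < self.potency_high < INACTIVE_UM:
            raise ValueError("require 0 < potency_low < potency_high < 1e6 µM")
        if self.n_assays < len(self.targets) * self.assays_per_target:
            raise ValueError(
                "n_assays must cover the vascular target features "
                f"({len(self.targets)} × {self.assays_per_target} assays)"
            )


def _rng(cfg: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _sample_potency(rng: np.random.Generator, cfg: GeneratorConfig, size=None):
    lo, hi = np.log10(cfg.potency_low), np.log10(cfg.potency_high)
    return 10.0 ** rng.uniform(lo, hi, size=size)


def make_annotations(cfg: GeneratorConfig) -> AnnotationTable:
    """Annotation table: two assays per vascular target + background.

    Vascular assays carry the target's gene symbol and an up/down
    direction parsed from the feature name; background assays carry
    synthetic gene symbols (three assays per gene) and no target
    feature, so they participate in pathway mapping but not in VBS.
    """
    anns = []
    for t in cfg.targets:
        direction = (
            Direction.UPDOWN
            if t.endswith("updown")
            else Direction.UP if t.endswith("up") else Direction.DOWN
        )
        for k in range(cfg.assays_per_target):
            anns.append(
                AssayAnnotation(
                    assay_id=f"VAS_{t}_{k}",
                    platform="BSK" if "2_" not in t else "NVS",
                    cell_system="synthetic",
                    gene_symbol=TARGET_GENES.get(t, t.split("_")[0]),
                    target_feature=t,
                    direction=direction,
                    measure=Measure.LEC if k else Measure.AC50,
                )
            )
    n_background = cfg.n_assays - len(anns)
    for j in range(n_background):
        anns.append(
            AssayAnnotation(
                assay_id=f"BG_{j:03d}",
                platform="SYN",
                cell_system="synthetic",
                gene_symbol=f"G{j // 3:03d}",
                target_feature="",
                direction=Direction.NA,
                measure=Measure.AC50,
            )
        )
    return AnnotationTable(anns)


def generate_hts(
    cfg: GeneratorConfig = GeneratorConfig(),
) -> tuple[PotencyMatrix, AnnotationTable, pd.DataFrame]:
    """Generate a potency matrix with planted vascular actives.

    Every planted active hits the shared vascular core targets with
    probability ``p_core`` each, its own mechanism pair with
    ``p_own_mechanism``, and the opposite pair with
    ``p_other_mechanism``; targets are topped up at random until at
    least ``min_target_features`` of the six are hit.  All remaining
    cells receive background false hits at ``background_hit_rate``.
    Returns ``(matrix, annotations, truth)`` where ``truth`` is indexed
    by chemical with boolean ``active`` and string ``mechanism``
    ("PAS", "chemokine", or "" for inactives).  Deterministic given
    ``cfg.seed``.
    """
    annotations = make_annotations(cfg)
    assay_ids = [a.assay_id for a in annotations]
    chemicals = [f"CHEM_{i:04d}" for i in range(cfg.n_chemicals)]
    rng = _rng(cfg, stream=1)

    n_active = int(round(cfg.active_fraction * cfg.n_chemicals))
    active_idx = rng.choice(cfg.n_chemicals, size=n_active, replace=False)
    mechanisms = np.full(cfg.n_chemicals, "", dtype=object)
    shuffled = rng.permutation(active_idx)
    mechanisms[shuffled[: n_active // 2]] = "PAS"
    mechanisms[shuffled[n_active // 2:]] = "chemokine"

    target_assays = {t: annotations.assays_for_target(t) for t in cfg.targets}
    col_of = {a: j for j, a in enumerate(assay_ids)}
    values = np.full((cfg.n_chemicals, cfg.n_assays), INACTIVE_UM)

    for i in np.sort(active_idx):
        mech = mechanisms[i]
        own = MECHANISM_TARGETS[mech]
        other = MECHANISM_TARGETS["chemokine" if mech == "PAS" else "PAS"]
        hit_targets = set()
        for t in CORE_TARGETS:
            if rng.random() < cfg.p_core:
                hit_targets.add(t)
        for t in own:
            if rng.random() < cfg.p_own_mechanism:
                hit_targets.add(t)
        for t in other:
            if rng.random() < cfg.p_other_mechanism:
                hit_targets.add(t)
        missing = [t for t in cfg.targets if t not in hit_targets]
        while len(hit_targets) < cfg.min_target_features:
            pick = missing.pop(int(rng.integers(len(missing))))
            hit_targets.add(pick)
        for t in cfg.targets:
            if t in hit_targets:
                for a in target_assays[t]:
                    values[i, col_of[a]] = _sample_potency(rng, cfg)

    background = rng.random(values.shape) < cfg.background_hit_rate
    background &= values >= INACTIVE_UM  # never overwrite planted hits
    values[background] = _sample_potency(rng, cfg, size=int(background.sum()))

    matrix = PotencyMatrix(
        pd.DataFrame(values, index=chemicals, columns=assay_ids),
        provenance=f"synthetic screen, seed={cfg.seed}",
    )
    truth = pd.DataFrame(
        {
            "active": [m != "" for m in mechanisms],
            "mechanism": list(mechanisms),
        },
        index=pd.Index(chemicals, name="chemical"),
    )
    return matrix, annotations, truth


def generate_endpoints(
    cfg: GeneratorConfig,
    truth: pd.DataFrame,
) -> tuple[list[EndpointRecord], pd.DataFrame]:
    """Generate prenatal endpoint records for the planted actives.

    PAS-linked actives receive rabbit fetal-loss records with
    probability ``p_endpoint_pas``; chemokine-linked actives receive rat
    skeletal records with ``p_endpoint_chemokine``; each penetrant
    chemical additionally gains a cross-species record with probability
    ``label_noise`` (destroying its species-only status).  Returns the
    records plus a ground-truth frame (indexed by active chemical) with
    the planted species label ("rabbit-only" / "rat-only").  The
    endpoint universe — chemicals tested in both species — is the
    planted active set.
    """
    rng = _rng(cfg, stream=2)
    records: list[EndpointRecord] = []
    labels = {}
    actives = truth.index[truth["active"]]
    penetrance = {"PAS": cfg.p_endpoint_pas, "chemokine": cfg.p_endpoint_chemokine}
    for chem in actives:
        mech = truth.at[chem, "mechanism"]
        labels[chem] = f"{MECHANISM_SPECIES[mech]}-only"
        if rng.random() >= penetrance[mech]:
            continue  # non-penetrant: tested, no recorded effect
        species = MECHANISM_SPECIES[mech]
        cats = MECHANISM_CATEGORIES[mech]
        n_cat = 1 + int(rng.random() < 0.5)
        chosen = rng.choice(len(cats), size=n_cat, replace=False)
        lel = float(10 ** rng.uniform(0, 3))
        for c in chosen:
            records.append(
                EndpointRecord(
                    chemical=str(chem),
                    species=species,
                    category=cats[int(c)],
                    lel=round(lel, 2),
                )
            )
        if rng.random() < cfg.label_noise:
            other_mech = "chemokine" if mech == "PAS" else "PAS"
            records.append(
                EndpointRecord(
                    chemical=str(chem),
                    species=MECHANISM_SPECIES[other_mech],
                    category=MECHANISM_CATEGORIES[other_mech][
                        int(rng.integers(2))
                    ],
                    lel=round(lel, 2),
                )
            )
    truth_labels = pd.DataFrame(
        {"planted_label": [labels[c] for c in actives]},
        index=pd.Index(list(actives), name="chemical"),
    )
    return records, truth_labels


def generate_pathways(
    cfg: GeneratorConfig = GeneratorConfig(),
    n_background_pathways: int = 6,
    genes_per_pathway: int = 10,
) -> list[PathwayMap]:
    """Gene-set fixtures: one PAS pathway, one chemokine pathway, and
    random background pathways over the synthetic background genes."""
    rng = _rng(cfg, stream=3)
    n_bg_genes = max((cfg.n_assays - len(cfg.targets) * cfg.assays_per_target) // 3, 1)
    bg_genes = [f"G{j:03d}" for j in range(n_bg_genes)]
    pathways = [
        PathwayMap(
            pathway_id="PAS_fibrinolysis",
            genes=("SERPINE1", "PLAUR", *bg_genes[:4]),
            source="GO",
            description="GO:Process fibrinolysis (synthetic)",
        ),
        PathwayMap(
            pathway_id="chemokine_signaling",
            genes=("CCL2", "CXCL10", *bg_genes[4:8]),
            source="KEGG",
            description="KEGG: chemokine signaling (synthetic)",
        ),
    ]
    for k in range(n_background_pathways):
        picks = rng.choice(
            n_bg_genes, size=min(genes_per_pathway, n_bg_genes), replace=False
        )
        pathways.append(
            PathwayMap(
                pathway_id=f"BG_pathway_{k}",
                genes=tuple(bg_genes[int(j)] for j in np.sort(picks)),
                source="IPA",
                description=f"IPA: background process {k} (synthetic)",
            )
        )
    return pathways


def endpoint_records_frame(records: Sequence[EndpointRecord]) -> pd.DataFrame:
    """Records as a writable table (one row per chemical × species,
    categories ';'-joined) in the endpoint-file layout."""
    grouped: dict[tuple[str, str], dict] = {}
    for r in records:
        key = (r.chemical, r.species)
        entry = grouped.setdefault(
            key, {"chemical": r.chemical, "species": r.species,
                  "categories": [], "lel": r.lel}
        )
        if r.category not in entry["categories"]:
            entry["categories"].append(r.category)
    rows = [
        {
            "chemical": e["chemical"],
            "species": e["species"],
            "category": "; ".join(e["categories"]),
            "lel": e["lel"] if e["lel"] is not None else "",
        }
        for e in grouped.values()
    ]
    return pd.DataFrame(rows, columns=["chemical", "species", "category", "lel"])
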