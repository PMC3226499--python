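"""Prenatal developmental endpoint records and species-specific labels.

Guideline prenatal studies in rat and rabbit report categorical
developmental endpoints per chemical (fetal loss, skeletal defects,
weight reduction, ...) with a lowest effect level (LEL, mg/kg/day).
This module validates such records against a controlled category
vocabulary, derives species-specific positive sets (chemicals toxic in
one species but not the other), and computes phenotype prevalence
summaries over a chemical set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

SPECIES = ("rat", "rabbit")

#: Controlled endpoint category vocabulary (extensible via ``extra``
#: arguments); seeded from the categories observed in prenatal rat and
#: rabbit guideline studies of the screened pesticide library.
DEFAULT_VOCABULARY: frozenset[str] = frozenset(
    {
        "embryo fetal loss",
        "maternal pregnancy loss",
        "fetal weight reduction",
        "general fetal pathology",
        "skeletal: axial",
        "skeletal: appendicular",
        "skeletal: cranial",
        "urogenital: renal",
        "urogenital: ureteric",
        "neurosensory: eye",
        "trunk: body wall",
    }
)

#: Categories counted as direct embryo effects (excludes maternal
#: pregnancy loss, whose maternal vs embryonic origin is ambiguous).
DIRECT_EMBRYO_CATEGORIES: frozenset[str] = frozenset(
    DEFAULT_VOCABULARY - {"maternal pregnancy loss"}
)

FETAL_LOSS_CATEGORIES: frozenset[str] = frozenset(
    {"embryo fetal loss", "maternal pregnancy loss"}
)


def _norm(s: str) -> str:
    return " ".join(str(s).strip().lower().split())


@dataclass(frozen=True)
class EndpointRecord:
    """One in vivo observation: chemical, species, category, optional LEL."""

    chemical: str
    species: str
    category: str
    lel: float | None = None

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.lel is not None and self.lel <= 0:
            raise ValueError(f"LEL must be > 0 mg/kg/day, got {self.lel!r}")


def load_endpoints(
    path: str | Path,
    vocabulary: Iterable[str] = DEFAULT_VOCABULARY,
) -> list[EndpointRecord]:
    """Read endpoint records from a delimited table.

    Expects a header with at least ``chemical, species, category, lel``
    (extra columns ignored).  A category cell may hold several
    categories joined by ";"; each is validated against the vocabulary.
    Unknown species or categories are rejected with the line number.
    """
    vocab = {_norm(v) for v in vocabulary}
    sep = "\t" if str(path).endswith((".tsv", ".txt", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"chemical", "species", "category", "lel"}
    cols = {c.strip().lower(): c for c in df.columns}
    missing = required - set(cols)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records: list[EndpointRecord] = []
    for i, row in df.iterrows():
        lineno = i + 2  # header is line 1
        chemical = str(row[cols["chemical"]]).strip()
        species = _norm(row[cols["species"]])
        if species not in SPECIES:
            raise ValueError(
                f"{path}:{lineno}: unknown species {row[cols['species']]!r}"
            )
        lel_cell = str(row[cols["lel"]]).strip()
        lel = float(lel_cell) if lel_cell else None
        for part in str(row[cols["category"]]).split(";"):
            category = _norm(part)
            if not category:
                continue
            if category not in vocab:
                raise ValueError(
                    f"{path}:{lineno}: category {part.strip()!r} not in "
                    "vocabulary"
                )
            records.append(
                EndpointRecord(
                    chemical=chemical, species=species, category=category, lel=lel
                )
            )
    return records


@dataclass
class SpeciesLabelSet:
    """Species-specific positive sets over a tested-in-both universe.

    ``rabbit_only_pos`` / ``rat_only_pos`` hold chemicals positive in
    exactly one species; ``negatives`` maps each contrast to the rest of
    the universe (the model negatives for that signature).
    """

    tested_both: list[str]
    rabbit_only_pos: list[str]
    rat_only_pos: list[str]
    negatives: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        universe = set(self.tested_both)
        rabbit, rat = set(self.rabbit_only_pos), set(self.rat_only_pos)
        if rabbit & rat:
            raise ValueError("rabbit-only and rat-only sets must be disjoint")
        if not (rabbit <= universe and rat <= universe):
            raise ValueError("only-positive sets must lie in the universe")


def species_specific_sets(
    records: Iterable[EndpointRecord],
    universe: Sequence[str],
    categories: Iterable[str] | None = None,
) -> SpeciesLabelSet:
    """Split a tested-in-both-species universe into species-only positives.

    A chemical is species-X-positive iff it has ≥1 record in species X
    whose category falls in ``categories`` (default: the whole
    vocabulary, i.e. any developmental record counts, maternal pregnancy
    loss included; pass :data:`DIRECT_EMBRYO_CATEGORIES` to restrict to
    direct embryo effects).  X-only means positive in X and negative in
    the other species.  Records for chemicals outside the universe are
    logged and excluded.  Order and duplication of records are
    irrelevant; output preserves universe order.
    """
    if not universe:
        raise ValueError("universe must be nonempty")
    allowed = (
        {_norm(c) for c in categories} if categories is not None else None
    )
    ukeys = {_norm(c): c for c in universe}
    positive: dict[str, set[str]] = {s: set() for s in SPECIES}
    for rec in records:
        key = _norm(rec.chemical)
        if key not in ukeys:
            logger.info("record for chemical outside universe: %r", rec.chemical)
            continue
        if allowed is not None and _norm(rec.category) not in allowed:
            continue
        positive[rec.species].add(key)
    rabbit_only = [
        c for c in universe
        if _norm(c) in positive["rabbit"] and _norm(c) not in positive["rat"]
    ]
    rat_only = [
        c for c in universe
        if _norm(c) in positive["rat"] and _norm(c) not in positive["rabbit"]
    ]
    negatives = {
        "rabbit-only": [c for c in universe if c not in set(rabbit_only)],
        "rat-only": [c for c in universe if c not in set(rat_only)],
    }
    return SpeciesLabelSet(
        tested_both=list(universe),
        rabbit_only_pos=rabbit_only,
        rat_only_pos=rat_only,
        negatives=negatives,
    )


def phenotype_prevalence(
    records: Iterable[EndpointRecord],
    categories: Iterable[str],
    chemicals: Sequence[str] | None = None,
) -> tuple[int, float]:
    """Count chemicals with ≥1 record in the given categories.

    Counting is at chemical level: repeated categories for one chemical
    count once.  The denominator is ``chemicals`` when given, else the
    distinct chemicals present in ``records``.  Returns
    ``(count, fraction)``.
    """
    cats = {_norm(c) for c in categories}
    if not cats:
        raise ValueError("category list must be nonempty")
    records = list(records)
    if chemicals is None:
        chemicals = list(dict.fromkeys(r.chemical for r in records))
    if not chemicals:
        raise ValueError("chemical set must be nonempty")
    ckeys = {_norm(c) for c in chemicals}
    having = {
        _norm(r.chemical)
        for r in records
        if _norm(r.chemical) in ckeys and _norm(r.category) in cats
    }
    count = len(having)
    return count, count / len(ckeys)
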