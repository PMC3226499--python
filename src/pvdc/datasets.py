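"""Packaged reference tables.

Small transcriptions of the published reference tables used throughout
the tests and the worked examples: the expanded biochemical vascular
target screen (14 chemicals × 7 targets, with VBS and pVDC/non-pVDC
grouping), the two reference antiangiogenic compounds (thalidomide and
5HPP-33), and the rabbit- and rat-specific prenatal endpoint tables.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .hts_data import INACTIVE_UM, PotencyMatrix
from .toxref import EndpointRecord, load_endpoints

_VASCULAR_TARGET_ASSAYS = (
    "VEGFR1", "VEGFR2", "VEGFR3", "TIE2", "EphB2", "PI3Ka", "PTEN",
)


def _data_path(name: str) -> Path:
    return Path(resources.files("pvdc.data") / name)


def load_reference_vascular_targets() -> tuple[PotencyMatrix, pd.DataFrame]:
    """The expanded biochemical vascular-target screen.

    Returns ``(matrix, meta)``: a 14-chemical × 7-target potency matrix
    (AC50, µM; blanks were inactive) and a metadata frame indexed by
    chemical with the published ``vbs`` and ``group`` ("pvdc" /
    "non_pvdc").
    """
    df = pd.read_csv(_data_path("reference_vascular_targets.csv"))
    meta = df.set_index("chemical")[["group", "vbs"]]
    mat = (
        df.set_index("chemical")[list(_VASCULAR_TARGET_ASSAYS)]
        .astype(float)
        .fillna(INACTIVE_UM)
    )
    return PotencyMatrix(mat, provenance="reference vascular target screen"), meta


def load_reference_antiangiogenic() -> pd.DataFrame:
    """Thalidomide and 5HPP-33 activity across the six vascular targets.

    Potencies are µM (LEC except the TIE2 column, an AC50); NaN means no
    change.  Indexed by chemical with the published ``vbs``.
    """
    return pd.read_csv(
        _data_path("reference_antiangiogenic.csv"), index_col="chemical"
    )


def load_rabbit_specific_endpoints() -> list[EndpointRecord]:
    """Prenatal endpoint records for the 22 rabbit-only positives."""
    return load_endpoints(_data_path("rabbit_specific_endpoints.csv"))


def load_rat_specific_endpoints() -> list[EndpointRecord]:
    """Prenatal endpoint records for the 21 rat-only positives."""
    return load_endpoints(_data_path("rat_specific_endpoints.csv"))


def load_rabbit_specific_meta() -> pd.DataFrame:
    """Chemical-level view of the rabbit-only table (vbs per chemical)."""
    df = pd.read_csv(_data_path("rabbit_specific_endpoints.csv"))
    return df.set_index("chemical")[["vbs"]]


def load_rat_specific_meta() -> pd.DataFrame:
    """Chemical-level view of the rat-only table (vbs per chemical)."""
    df = pd.read_csv(_data_path("rat_specific_endpoints.csv"))
    return df.set_index("chemical")[["vbs"]]
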