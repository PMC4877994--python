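"""Shared sample-sheet container for paired LINE-1 / LUMA methylation values.

The working in-memory representation throughout the package is a pandas
DataFrame ("sample sheet") with one row per biological sample and the columns

=============  =======================================================
column         meaning
=============  =======================================================
sample_id      unique sample label
subset         data subset / tissue (e.g. ``MCF7``, ``SHSY5Y``, ``blood``)
treatment      treatment-condition label (``Untreated`` for blood cohorts)
line1_pct      calibrated LINE-1 methylation, % (may fall outside [0, 100])
luma_pct       calibrated LUMA methylation, %
qc_excluded    boolean, True if any quality rule fired
qc_reason      semicolon-joined list of fired rules ("" if retained)
=============  =======================================================

:class:`MethylSample` is the record-level view of one row.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

SHEET_COLUMNS = [
    "sample_id",
    "subset",
    "treatment",
    "line1_pct",
    "luma_pct",
    "qc_excluded",
    "qc_reason",
]


@dataclass
class MethylSample:
    """One biological sample with its paired assay readouts.

    Calibrated values are reported even when the affine control calibration
    maps them outside [0, 100]; such values are flagged upstream, never
    clipped, so that agreement statistics see the raw linear transform.
    """

    sample_id: str
    subset: str
    treatment: str
    line1_pct: float
    luma_pct: float
    qc_excluded: bool = False
    qc_reason: str = ""


def to_frame(samples: list[MethylSample]) -> pd.DataFrame:
    """Assemble records into the canonical sample sheet."""
    return pd.DataFrame([vars(s) for s in samples], columns=SHEET_COLUMNS)


def from_frame(df: pd.DataFrame) -> list[MethylSample]:
    return [MethylSample(**{k: row[k] for k in SHEET_COLUMNS}) for _, row in df.iterrows()]


def validate_sheet(df: pd.DataFrame) -> pd.DataFrame:
    """Check the sheet has the required columns; fill optional QC columns."""
    df = df.copy()
    for col in ("sample_id", "subset", "line1_pct", "luma_pct"):
        if col not in df.columns:
            raise ValueError(f"sample sheet is missing required column {col!r}")
    if "treatment" not in df.columns:
        df["treatment"] = "Untreated"
    if "qc_excluded" not in df.columns:
        df["qc_excluded"] = False
    if "qc_reason" not in df.columns:
        df["qc_reason"] = ""
    return df


def retained(df: pd.DataFrame) -> pd.DataFrame:
    """Rows that passed all quality filters."""
    return df.loc[~df["qc_excluded"].astype(bool)].reset_index(drop=True)


def read_sheet(path) -> pd.DataFrame:
    return validate_sheet(pd.read_csv(path))


def write_sheet(df: pd.DataFrame, path) -> None:
    validate_sheet(df).to_csv(path, index=False)
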