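"""Pyrogram peak heights -> calibrated % methylation for LINE-1 and LUMA.

LUMA quantifies global methylation from a pair of restriction digestions
(methylation-sensitive HpaII vs insensitive MspI, each normalized by the
methylation-insensitive MfeI) read out by pyrosequencing with the fixed
dispensation order

    step 1  dATPaS        step 4  dGTP + dCTP (second fill-in)
    step 2  dGTP + dCTP   step 5  water blank
    step 3  dTTP          step 6  dATPaS (carry-over check)

For each reaction the enzyme ratio is (dGTP + dCTP) / mean(dATP, dTTP), i.e.
``peak2 / mean(peak1, peak3)``; methylation is
``(1 - (HpaII ratio) / (MspI ratio)) * 100``.

LINE-1 methylation is the mean across four CpG sites of a pyrosequenced
retrotransposon promoter amplicon, measured in duplicate within a run and in
two independent runs that are averaged.  Both assays are finally calibrated
against fully unmethylated / fully methylated control DNA by the affine map
that sends the control readings to 0 and 100 %.

Quality rules (any firing rule excludes the sample, the reason records all
fired rules):

* informative peak heights (steps 1-3) below 2 (blood) or 1 (cell samples);
* MspI/MfeI ratio above 4.2 (incomplete digestion);
* peak 6 more than 25 % of peak 1 (strictly more; carry-over signal).

Threshold comparisons are strict: a peak height exactly at the threshold is
retained, a peak-6 fraction of exactly 25 % is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .samples import SHEET_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "PyrogramRecord",
    "Line1Read",
    "ControlSet",
    "enzyme_ratio",
    "luma_methylation",
    "luma_qc",
    "line1_methylation",
    "calibrate",
    "interassay_cv",
    "quantify",
]

#: informative-peak height threshold by specimen kind
PEAK_HEIGHT_MIN = {"blood": 2.0, "cell": 1.0}
MSPI_RATIO_MAX = 4.2
PEAK6_FRACTION_MAX = 0.25


class QuantificationError(ValueError):
    """Raised when peak heights cannot be turned into a methylation value."""


@dataclass
class PyrogramRecord:
    """Raw per-dispensation peak heights of one digestion reaction."""

    sample_id: str
    subset: str
    run_id: str
    reaction: str  # "HpaII+MfeI" or "MspI+MfeI"
    peaks: list[float]

    def __post_init__(self):
        if len(self.peaks) != 6:
            raise ValueError(f"{self.sample_id}: expected 6 peaks, got {len(self.peaks)}")
        if any(p < 0 for p in self.peaks):
            raise ValueError(f"{self.sample_id}: negative peak height")


@dataclass
class Line1Read:
    """Per-CpG % methylation of one pyrosequencing read (four CpG sites)."""

    sample_id: str
    subset: str
    run_id: str
    cpg_pct: list[float]
    conversion_ok: bool = True

    def __post_init__(self):
        if len(self.cpg_pct) != 4:
            raise ValueError(f"{self.sample_id}: expected 4 CpG values")
        if any(not (0 <= c <= 100) for c in self.cpg_pct):
            raise ValueError(f"{self.sample_id}: CpG % outside [0, 100]")


@dataclass
class ControlSet:
    """Raw readings of the 0 % / 100 % control DNA of one run."""

    run_id: str
    assay: str  # "LINE1" or "LUMA"
    low_pct: float
    high_pct: float

    def __post_init__(self):
        if self.high_pct <= self.low_pct:
            raise ValueError(
                f"controls for run {self.run_id}: high ({self.high_pct}) must exceed low ({self.low_pct})"
            )


def enzyme_ratio(record: PyrogramRecord) -> float:
    """(dGTP + dCTP) / mean(dATP, dTTP) of one reaction.

    Uses the first dGTP+dCTP dispensation (step 2) as the informative
    fill-in signal over the mean of the dATP (step 1) and dTTP (step 3)
    reference peaks.
    """
    denom = 0.5 * (record.peaks[0] + record.peaks[2])
    if denom <= 0:
        raise QuantificationError(
            f"{record.sample_id}: zero dATP/dTTP reference signal in {record.reaction}"
        )
    return record.peaks[1] / denom


def luma_methylation(hpaii_rec: PyrogramRecord, mspi_rec: PyrogramRecord) -> float:
    """Raw LUMA methylation % = (1 - (HpaII/MfeI)/(MspI/MfeI)) * 100.

    The HpaII/MspI quotient is 1 for completely unmethylated DNA
    (methylation 0 %) and approaches 0 for completely methylated DNA
    (methylation 100 %).
    """
    if hpaii_rec.sample_id != mspi_rec.sample_id:
        raise QuantificationError(
            f"mismatched sample ids: {hpaii_rec.sample_id!r} vs {mspi_rec.sample_id!r}"
        )
    r_hpa = enzyme_ratio(hpaii_rec)
    r_msp = enzyme_ratio(mspi_rec)
    if r_msp == 0:
        raise QuantificationError(f"{mspi_rec.sample_id}: MspI/MfeI ratio is zero")
    return (1.0 - r_hpa / r_msp) * 100.0


def luma_qc(hpaii_rec: PyrogramRecord, mspi_rec: PyrogramRecord,
            subset_kind: str) -> tuple[bool, list[str]]:
    """Apply the LUMA exclusion rules; returns (keep, fired_rules).

    QC never raises on record content; every rule is evaluated so the reason
    enumerates all fired rules, and the retained set is independent of rule
    order.
    """
    if subset_kind not in PEAK_HEIGHT_MIN:
        raise ValueError(f"subset_kind must be 'blood' or 'cell', got {subset_kind!r}")
    threshold = PEAK_HEIGHT_MIN[subset_kind]
    fired = []
    informative = [p for rec in (hpaii_rec, mspi_rec) for p in rec.peaks[:3]]
    if any(p < threshold for p in informative):
        fired.append(f"peak_height<{threshold:g}")
    try:
        if enzyme_ratio(mspi_rec) > MSPI_RATIO_MAX:
            fired.append(f"MspI/MfeI_ratio>{MSPI_RATIO_MAX}")
    except QuantificationError:
        fired.append("MspI/MfeI_ratio_undefined")
    for rec in (hpaii_rec, mspi_rec):
        if rec.peaks[0] > 0 and rec.peaks[5] / rec.peaks[0] > PEAK6_FRACTION_MAX:
            fired.append("peak6>25%_of_peak1")
            break
    return (len(fired) == 0, fired)


def line1_methylation(reads: list[Line1Read]) -> float:
    """Raw LINE-1 % for one sample: CpG mean -> duplicate mean -> run mean.

    Reads failing the bisulfite-conversion flag are dropped with a log entry;
    if all reads fail, the sample is excluded (QuantificationError).
    """
    if not reads:
        raise QuantificationError("no LINE-1 reads supplied")
    sample_id = reads[0].sample_id
    kept = [r for r in reads if r.conversion_ok]
    n_dropped = len(reads) - len(kept)
    if n_dropped:
        logger.info("line1_methylation: %s: dropped %d reads failing conversion QC",
                    sample_id, n_dropped)
    if not kept:
        raise QuantificationError(f"{sample_id}: all reads fail bisulfite-conversion QC")
    by_run: dict[str, list[float]] = {}
    for r in kept:
        by_run.setdefault(r.run_id, []).append(float(np.mean(r.cpg_pct)))
    run_means = [float(np.mean(v)) for v in by_run.values()]
    return float(np.mean(run_means))


def calibrate(raw: float, controls: ControlSet) -> tuple[float, bool]:
    """Two-point control calibration; returns (calibrated, in_range_flag).

    Affine map sending the unmethylated control reading to 0 % and the
    methylated control reading to 100 %.  Values landing outside [0, 100]
    are returned unchanged but flagged (never clipped), so that downstream
    agreement statistics see the raw linear transform.
    """
    value = (raw - controls.low_pct) / (controls.high_pct - controls.low_pct) * 100.0
    return value, 0.0 <= value <= 100.0


def interassay_cv(duplicate_pairs: list[tuple[float, float]]) -> float:
    """Mean of per-pair coefficients of variation (%), CV = SD/mean * 100.

    Pairs with zero mean are skipped with a warning.  The per-pair SD uses
    the n-1 denominator, so a pair (v1, v2) has SD = |v1 - v2| / sqrt(2).
    """
    if not duplicate_pairs:
        raise ValueError("need at least one duplicate pair")
    cvs = []
    for v1, v2 in duplicate_pairs:
        mean = 0.5 * (v1 + v2)
        if mean == 0:
            logger.warning("interassay_cv: skipping zero-mean pair (%g, %g)", v1, v2)
            continue
        cvs.append(np.std([v1, v2], ddof=1) / mean * 100.0)
    if not cvs:
        raise ValueError("all duplicate pairs had zero mean")
    return float(np.mean(cvs))


# ---------------------------------------------------------------------------
# Table-level driver
# ---------------------------------------------------------------------------

def _pyrogram_records(pyro_df: pd.DataFrame) -> dict[str, dict[str, PyrogramRecord]]:
    peak_cols = [f"peak{i}" for i in range(1, 7)]
    out: dict[str, dict[str, PyrogramRecord]] = {}
    for _, row in pyro_df.iterrows():
        rec = PyrogramRecord(row["sample_id"], row.get("subset", ""), row["run_id"],
                             row["reaction"], [float(row[c]) for c in peak_cols])
        out.setdefault(rec.sample_id, {})[rec.reaction] = rec
    return out


def _control_lookup(controls_df: pd.DataFrame) -> dict[tuple[str, str], ControlSet]:
    out = {}
    for _, row in controls_df.iterrows():
        cs = ControlSet(row["run_id"], row["assay"], float(row["low_pct"]), float(row["high_pct"]))
        out[(cs.run_id, cs.assay)] = cs
    return out


def subset_kind(subset: str) -> str:
    """Specimen kind for the peak-height QC threshold."""
    return "blood" if str(subset).lower() == "blood" else "cell"


def quantify(pyro_df: pd.DataFrame, line1_df: pd.DataFrame,
             controls_df: pd.DataFrame) -> pd.DataFrame:
    """Full quantification: peak tables -> calibrated sample sheet.

    Input layouts (CSV-compatible):

    * ``pyro_df``: sample_id, subset, run_id, reaction, peak1..peak6
    * ``line1_df``: sample_id, subset, run_id, cpg1..cpg4, conversion_ok
    * ``controls_df``: run_id, assay, low_pct, high_pct

    LINE-1 run means are calibrated with their own run's controls before
    averaging across runs; LUMA values are calibrated with the run's lambda
    controls.  Samples failing any QC rule are retained in the sheet with
    ``qc_excluded = True`` and the enumerated reasons.
    """
    controls = _control_lookup(controls_df)
    pyro = _pyrogram_records(pyro_df)
    cpg_cols = [f"cpg{i}" for i in range(1, 5)]
    rows = []
    for sample_id, grp in line1_df.groupby("sample_id", sort=False):
        subset = grp["subset"].iloc[0]
        reasons: list[str] = []
        reads = [
            Line1Read(sample_id, subset, row["run_id"],
                      [float(row[c]) for c in cpg_cols], bool(row["conversion_ok"]))
            for _, row in grp.iterrows()
        ]
        line1_cal: float = np.nan
        try:
            kept = [r for r in reads if r.conversion_ok]
            if not kept:
                raise QuantificationError(f"{sample_id}: all reads fail bisulfite-conversion QC")
            run_values = []
            for run_id in dict.fromkeys(r.run_id for r in kept):
                run_reads = [r for r in kept if r.run_id == run_id]
                raw = line1_methylation(run_reads)
                cal, in_range = calibrate(raw, controls[(run_id, "LINE1")])
                if not in_range:
                    logger.info("quantify: %s LINE-1 run %s calibrated outside [0,100]",
                                sample_id, run_id)
                run_values.append(cal)
            line1_cal = float(np.mean(run_values))
        except QuantificationError:
            reasons.append("line1_conversion_qc")

        luma_cal: float = np.nan
        recs = pyro.get(sample_id, {})
        if "HpaII+MfeI" in recs and "MspI+MfeI" in recs:
            hpa, msp = recs["HpaII+MfeI"], recs["MspI+MfeI"]
            keep, fired = luma_qc(hpa, msp, subset_kind(subset))
            if not keep:
                reasons.extend(fired)
            else:
                raw = luma_methylation(hpa, msp)
                luma_cal, in_range = calibrate(raw, controls[(hpa.run_id, "LUMA")])
                if not in_range:
                    logger.info("quantify: %s LUMA calibrated outside [0,100]", sample_id)
        else:
            reasons.append("missing_luma_reaction")

        rows.append({
            "sample_id": sample_id,
            "subset": subset,
            "treatment": grp["treatment"].iloc[0] if "treatment" in grp else "Untreated",
            "line1_pct": line1_cal,
            "luma_pct": luma_cal,
            "qc_excluded": len(reasons) > 0,
            "qc_reason": ";".join(reasons),
        })
    return pd.DataFrame(rows, columns=SHEET_COLUMNS)
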