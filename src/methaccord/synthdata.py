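"""Synthetic paired-methylation data calibrated to the study conditions.

The generator emulates the three data subsets of the method-comparison study
(two treated human cell lines, MCF7 and SHSY5Y, and whole blood from three
clinical cohorts; 73 + 34 + 131 = 238 samples) at the sample level, and can
additionally invert the LUMA/LINE-1 quantification formulas to emit
pyrogram-level peak tables so that the whole quantification pipeline is
exercisable without any laboratory data.

Calibration model
-----------------
Each subset is a bivariate Gaussian copula over (LINE-1 %, LUMA %) whose
marginal means/SDs equal the published descriptive statistics.  The
correlation parameter is stored as a Spearman rho and converted to the
Pearson correlation of the underlying Gaussian through the exact bivariate
normal relation ``r = 2 sin(pi * rho / 6)``.

The *default* presets do not carry the published rank correlations verbatim:
a bivariate Gaussian that matches the published marginal SDs cannot
simultaneously reproduce the published Spearman rho and the published 95 %
limits of agreement (the rank statistic was computed on visibly non-Gaussian
real data).  Because every downstream pattern statistic — mixture components
of the interassay differences, Bayes boundaries, tissue tree, subset
regression slopes — is driven by the covariance, the defaults are calibrated
so that the implied SD of the interassay differences matches the published
limits of agreement exactly:

    sd(d)^2 = sd_line1^2 + sd_luma^2 - 2 * r * sd_line1 * sd_luma

which gives r = 0.8551 (MCF7), 0.9413 (SHSY5Y), 0.3218 (blood); the blood
value is practically identical to the published rank correlation.

Treatment conditions replicate the published exposure plan (replicate counts
per condition).  Additive per-condition shifts are free parameters chosen so
demethylating agents (5-Aza-CdR, RG108) lower and methyl-donors (SAM, DCP)
raise methylation; shifts are centred to zero weighted mean per subset and
the within-condition variance is shrunk accordingly, so the subset-level
marginals and covariance remain exactly the calibrated ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SubsetPreset",
    "TreatmentPlan",
    "SyntheticConfig",
    "DEFAULT_PRESETS",
    "DEFAULT_PLANS",
    "default_config",
    "spearman_to_pearson",
    "generate_samples",
    "generate_pyrograms",
]


def spearman_to_pearson(rho: float) -> float:
    """Pearson correlation of a bivariate normal with Spearman rho.

    Exact for the bivariate Gaussian: r = 2 sin(pi * rho / 6).
    """
    return 2.0 * np.sin(np.pi * rho / 6.0)


@dataclass(frozen=True)
class SubsetPreset:
    """Marginal calibration of one data subset (% methylation units)."""

    name: str
    n: int
    mean_line1: float
    sd_line1: float
    mean_luma: float
    sd_luma: float
    rho_spearman: float
    range_line1: tuple[float, float]
    range_luma: tuple[float, float]

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError(f"preset {self.name}: n must be positive")
        if self.sd_line1 <= 0 or self.sd_luma <= 0:
            raise ValueError(f"preset {self.name}: SDs must be positive")
        if abs(self.rho_spearman) > 1:
            raise ValueError(f"preset {self.name}: |rho_spearman| must be <= 1")
        for mean, rng, tag in (
            (self.mean_line1, self.range_line1, "LINE-1"),
            (self.mean_luma, self.range_luma, "LUMA"),
        ):
            if not (rng[0] <= mean <= rng[1]):
                raise ValueError(f"preset {self.name}: {tag} range does not contain the mean")


@dataclass(frozen=True)
class TreatmentPlan:
    """One exposure condition of a cell line.

    ``effect_line1`` / ``effect_luma`` are additive shifts in % methylation
    applied to the condition's replicates (before centring, see module docs).
    """

    cell_line: str
    condition: str
    n_replicates: int
    effect_line1: float = 0.0
    effect_luma: float = 0.0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError(f"plan {self.cell_line}/{self.condition}: n_replicates >= 1 required")


@dataclass
class SyntheticConfig:
    presets: list[SubsetPreset]
    plans: list[TreatmentPlan] = field(default_factory=list)
    seed: int = 0
    clamp: bool = True
    center_shifts: bool = True
    #: fraction of LUMA pyrogram record pairs violating each QC rule, and of
    #: samples whose LINE-1 reads all fail the bisulfite-conversion flag
    qc_violation_fraction: float = 0.0
    #: SD of iid Gaussian jitter added to pyrogram peak heights (0 = exact
    #: round trip through the quantification formulas)
    peak_noise_sd: float = 0.0

    def plans_for(self, subset: str) -> list[TreatmentPlan]:
        return [p for p in self.plans if p.cell_line == subset]


# Default presets.  Marginals follow the published per-subset descriptive
# statistics; the correlation parameter is calibrated to the published limits
# of agreement (see module docstring).
DEFAULT_PRESETS: list[SubsetPreset] = [
    SubsetPreset("MCF7", 73, 60.96, 11.99, 67.80, 11.99, 0.8436,
                 (34.0, 76.18), (34.36, 78.34)),
    SubsetPreset("SHSY5Y", 34, 59.01, 11.54, 55.66, 11.99, 0.9360,
                 (31.91, 71.65), (24.89, 67.65)),
    SubsetPreset("blood", 131, 92.40, 2.75, 72.30, 3.10, 0.3087,
                 (77.90, 98.80), (61.90, 78.50)),
]

# Replicate counts per condition follow the published exposure plan.  The
# shifts themselves are synthetic free parameters: demethylating agents
# (5-Aza-CdR, RG108) lower methylation dose-pool-wise, the methyl donor SAM
# and the pollutant DCP raise it, methadone raises it mildly; combinations
# interpolate.  Both assays receive the same shift by default.
def _plan(cell, cond, n, eff):
    return TreatmentPlan(cell, cond, n, eff, eff)


DEFAULT_PLANS: list[TreatmentPlan] = [
    _plan("MCF7", "Untreated", 6, 0.0),
    _plan("MCF7", "DMSO", 7, 0.0),
    _plan("MCF7", "5-Aza-CdR", 9, -12.0),
    _plan("MCF7", "SAM", 7, 6.0),
    _plan("MCF7", "DCP", 5, 5.0),
    _plan("MCF7", "Methadone", 11, 3.0),
    _plan("MCF7", "RG108", 6, -8.0),
    _plan("MCF7", "5-Aza-CdR+SAM", 4, -5.0),
    _plan("MCF7", "5-Aza-CdR+DCP", 2, -7.0),
    _plan("MCF7", "5-Aza-CdR+Methadone", 9, -9.0),
    _plan("MCF7", "5-Aza-CdR+SAM+DCP", 2, -4.0),
    _plan("MCF7", "RG108+DCP", 2, -3.0),
    _plan("MCF7", "SAM+DCP", 3, 7.0),
    _plan("SHSY5Y", "Untreated", 7, 0.0),
    _plan("SHSY5Y", "DMSO", 7, 0.0),
    _plan("SHSY5Y", "5-Aza-CdR", 12, -10.0),
    _plan("SHSY5Y", "SAM", 1, 4.0),
    _plan("SHSY5Y", "Methadone", 3, 2.0),
    _plan("SHSY5Y", "5-Aza-CdR+SAM", 1, -4.0),
    _plan("SHSY5Y", "5-Aza-CdR+Methadone", 3, -8.0),
    _plan("blood", "Healthy", 83, 0.0),
    _plan("blood", "Opioid analgesics", 29, 0.0),
    _plan("blood", "Non-opioid analgesics", 19, 0.0),
]


def default_config(seed: int = 0, **kwargs) -> SyntheticConfig:
    """The study-condition configuration: 238 samples (73/34/131)."""
    return SyntheticConfig(presets=list(DEFAULT_PRESETS), plans=list(DEFAULT_PLANS),
                           seed=seed, **kwargs)


def _condition_table(preset: SubsetPreset, config: SyntheticConfig):
    """Per-condition (label, n, shift_line1, shift_luma) with centred shifts."""
    plans = config.plans_for(preset.name)
    if not plans:
        plans = [TreatmentPlan(preset.name, "Untreated", preset.n)]
    n_total = sum(p.n_replicates for p in plans)
    if n_total != preset.n:
        raise ValueError(
            f"preset {preset.name}: treatment plan covers {n_total} replicates, preset has n={preset.n}"
        )
    n_k = np.array([p.n_replicates for p in plans], dtype=float)
    s1 = np.array([p.effect_line1 for p in plans], dtype=float)
    s2 = np.array([p.effect_luma for p in plans], dtype=float)
    if config.center_shifts:
        s1 = s1 - np.average(s1, weights=n_k)
        s2 = s2 - np.average(s2, weights=n_k)
    return plans, n_k, s1, s2


def _within_condition_cov(preset: SubsetPreset, n_k, s1, s2):
    """Within-condition covariance so subset totals match the preset.

    Splits the target (marginal) variance into a between-condition part
    (from the centred shifts) and a within part; likewise for the covariance.
    Raises if the implied within-condition correlation is not in (-1, 1).
    """
    w = n_k / n_k.sum()
    tau11 = float(np.sum(w * s1**2))
    tau22 = float(np.sum(w * s2**2))
    tau12 = float(np.sum(w * s1 * s2))
    v1 = preset.sd_line1**2 - tau11
    v2 = preset.sd_luma**2 - tau22
    if v1 <= 0 or v2 <= 0:
        raise ValueError(
            f"preset {preset.name}: treatment shifts exceed the subset variance"
        )
    r_total = spearman_to_pearson(preset.rho_spearman)
    c_within = r_total * preset.sd_line1 * preset.sd_luma - tau12
    rho_w = c_within / np.sqrt(v1 * v2)
    if not (-1.0 < rho_w < 1.0):
        raise ValueError(
            f"preset {preset.name}: implied within-condition correlation {rho_w:.3f} "
            "is not positive definite"
        )
    return np.sqrt(v1), np.sqrt(v2), rho_w


def generate_samples(config: SyntheticConfig) -> pd.DataFrame:
    """Draw the paired sample sheet defined by ``config``.

    Returns the canonical sample sheet (see :mod:`methaccord.samples`) with
    ``qc_excluded = False`` everywhere: QC is exercised at the pyrogram level.
    Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    n_clamped = 0
    for preset in config.presets:
        plans, n_k, s1, s2 = _condition_table(preset, config)
        sd1_w, sd2_w, rho_w = _within_condition_cov(preset, n_k, s1, s2)
        for plan, sh1, sh2 in zip(plans, s1, s2):
            m = plan.n_replicates
            e1 = rng.standard_normal(m)
            e2 = rho_w * e1 + np.sqrt(1.0 - rho_w**2) * rng.standard_normal(m)
            line1 = preset.mean_line1 + sh1 + sd1_w * e1
            luma = preset.mean_luma + sh2 + sd2_w * e2
            if config.clamp:
                n_clamped += int(np.sum((line1 < 0) | (line1 > 100) | (luma < 0) | (luma > 100)))
                line1 = np.clip(line1, 0.0, 100.0)
                luma = np.clip(luma, 0.0, 100.0)
            for j in range(m):
                rows.append({
                    "sample_id": f"{preset.name}_{plan.condition}_{j + 1}".replace(" ", ""),
                    "subset": preset.name,
                    "treatment": plan.condition,
                    "line1_pct": line1[j],
                    "luma_pct": luma[j],
                    "qc_excluded": False,
                    "qc_reason": "",
                })
    if n_clamped:
        logger.info("generate_samples: clamped %d draws to [0, 100]", n_clamped)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pyrogram-level generation (inverse of the quantification formulas)
# ---------------------------------------------------------------------------

#: default control readings: raw % reached by the fully methylated / fully
#: unmethylated controls of each assay (the methylated LINE-1 control reads
#: well below 100 due to PCR bias; the LUMA lambda-phage control reads 95.7)
LINE1_CONTROLS = (3.37, 75.08)
LUMA_CONTROLS = (0.0, 95.7)

#: dATP/dTTP reference peak height by specimen kind (arbitrary light units);
#: chosen high enough that clean records never trip the low-signal QC rule
_BASE_PEAK = {"blood": 25.0, "cell": 15.0}
_MSPI_RATIO = 2.0
_CPG_OFFSETS = np.array([0.4, -0.4, 0.2, -0.2])  # zero-mean per-site spread


def _raw_from_calibrated(pct: float, controls: tuple[float, float]) -> float:
    low, high = controls
    return low + pct * (high - low) / 100.0


def _luma_peaks(quotient_ratio: float, base: float, rng, noise_sd: float) -> list[float]:
    """Six dispensation peaks for one digestion reaction.

    Steps 1/3 are the dATP/dTTP reference fill-ins, steps 2/4 the two
    dGTP+dCTP signals, step 5 the water blank and step 6 the terminal dATP
    used in QC only.
    """
    g = quotient_ratio * base
    peaks = np.array([base, g, base, g, 0.0, 0.1 * base])
    if noise_sd > 0:
        peaks = peaks + rng.normal(0.0, noise_sd, size=6)
        peaks = np.clip(peaks, 0.0, None)
    return list(peaks)


def generate_pyrograms(samples: pd.DataFrame, config: SyntheticConfig):
    """Emit pyrogram peak tables whose quantification returns the targets.

    Returns ``(pyrograms, line1_reads, controls)`` DataFrames in the CSV
    layouts read by :mod:`methaccord.pyroquant`.  With
    ``config.peak_noise_sd == 0`` and ``config.qc_violation_fraction == 0``
    the round trip through :func:`methaccord.pyroquant.quantify` recovers
    every target value to floating-point accuracy.
    """
    bad = samples[(samples["luma_pct"] < 0) | (samples["luma_pct"] > 100)]
    if len(bad):
        raise ValueError(
            f"target LUMA methylation outside [0, 100] for {bad['sample_id'].iloc[0]!r}"
        )
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xB10)))
    pyro_rows, read_rows = [], []
    frac = config.qc_violation_fraction
    qc_rules = ("low_peaks", "high_mspi_ratio", "peak6")
    for _, s in samples.iterrows():
        kind = "blood" if s["subset"] == "blood" else "cell"
        base = _BASE_PEAK[kind]
        raw_luma = _raw_from_calibrated(s["luma_pct"], LUMA_CONTROLS)
        hpaii_quot = 1.0 - raw_luma / 100.0  # HpaII/MspI peak-ratio quotient
        hpa = _luma_peaks(_MSPI_RATIO * hpaii_quot, base, rng, config.peak_noise_sd)
        msp = _luma_peaks(_MSPI_RATIO, base, rng, config.peak_noise_sd)
        violate = frac > 0 and rng.random() < frac
        if violate:
            rule = qc_rules[rng.integers(len(qc_rules))]
            if rule == "low_peaks":
                scale = (0.5 if kind == "cell" else 1.5) / base
                hpa = [p * scale for p in hpa]
            elif rule == "high_mspi_ratio":
                msp[1] = msp[3] = 4.5 * base
            else:
                msp[5] = 0.5 * msp[0]
        for reaction, peaks in (("HpaII+MfeI", hpa), ("MspI+MfeI", msp)):
            pyro_rows.append({
                "sample_id": s["sample_id"], "subset": s["subset"], "run_id": "LUMA_R1",
                "reaction": reaction,
                **{f"peak{i + 1}": peaks[i] for i in range(6)},
            })
        raw_l1 = _raw_from_calibrated(s["line1_pct"], LINE1_CONTROLS)
        cpg = np.clip(raw_l1 + _CPG_OFFSETS, 0.0, 100.0)
        if cpg.mean() != raw_l1:  # offsets truncated near the scale ends
            cpg = np.full(4, raw_l1)
        conv_fail = frac > 0 and rng.random() < frac
        for run_id in ("L1", "L2"):
            for dup in (1, 2):
                read_rows.append({
                    "sample_id": s["sample_id"], "subset": s["subset"], "run_id": run_id,
                    "duplicate": dup,
                    **{f"cpg{i + 1}": cpg[i] for i in range(4)},
                    "conversion_ok": not conv_fail,
                })
    controls = pd.DataFrame([
        {"run_id": "LUMA_R1", "assay": "LUMA",
         "low_pct": LUMA_CONTROLS[0], "high_pct": LUMA_CONTROLS[1]},
        {"run_id": "L1", "assay": "LINE1",
         "low_pct": LINE1_CONTROLS[0], "high_pct": LINE1_CONTROLS[1]},
        {"run_id": "L2", "assay": "LINE1",
         "low_pct": LINE1_CONTROLS[0], "high_pct": LINE1_CONTROLS[1]},
    ])
    return pd.DataFrame(pyro_rows), pd.DataFrame(read_rows), controls
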