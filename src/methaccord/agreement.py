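"""Per-subset agreement statistics between the two methylation assays.

Implements the classical laboratory method-comparison battery: descriptive
statistics, paired Wilcoxon signed-rank tests, Spearman correlation with
percentile-bootstrap confidence intervals, the Bland-Altman 95 % limits of
agreement with fixed and proportional bias, Kolmogorov-Smirnov normality
assessment of the differences, and a mixed two-way repeated-measures ANOVA
(assay as within-subject factor, data subset as between-subject factor) with
Bonferroni-corrected post-hoc tests.

Conventions
-----------
* differences are d = LINE-1 % - LUMA %;
* limits of agreement use the constant 1.96 (not a t quantile);
* the fixed-bias confidence interval uses the t distribution;
* the default normality test is the Lilliefors-corrected KS test, because
  the normal parameters are estimated from the data; the naive KS test
  against the fitted normal is available via ``lilliefors=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

__all__ = [
    "AgreementReport",
    "bland_altman",
    "spearman_bootstrap",
    "paired_tests",
    "rm_anova",
    "agreement_report",
    "subset_reports",
]


@dataclass
class AgreementReport:
    """Agreement statistics of one data subset (all in % methylation)."""

    subset: str
    n: int
    mean_line1: float
    sd_line1: float
    mean_luma: float
    sd_luma: float
    wilcoxon_V: float
    wilcoxon_p: float
    spearman_rho: float
    rho_ci: tuple[float, float]
    rho_p: float
    mean_diff: float                  # fixed bias
    diff_ci: tuple[float, float]
    t_p: float                        # one-sample t test of mean_diff vs 0
    ks_D: float
    ks_p: float
    loa: tuple[float, float]          # mean_diff -/+ 1.96 SD(d)
    prop_slope: float | None          # proportional bias
    slope_ci: tuple[float, float] | None
    slope_p: float | None

    def to_dict(self) -> dict:
        return asdict(self)


def _diffs(df: pd.DataFrame) -> np.ndarray:
    return (df["line1_pct"] - df["luma_pct"]).to_numpy(dtype=float)


def bland_altman(df: pd.DataFrame) -> dict:
    """Fixed and proportional bias of LINE-1 vs LUMA.

    Returns the bias block of :class:`AgreementReport`: mean difference with
    t-based CI and one-sample t test, 95 % limits of agreement
    (mean +- 1.96 SD), and the OLS slope of the differences on the pairwise
    averages with CI and two-sided p.  With fewer than 3 pairs the problem is
    degenerate and a ValueError is raised; with zero variance of the averages
    the slope is undefined and reported as ``None``.
    """
    d = _diffs(df)
    n = len(d)
    if n < 3:
        raise ValueError(f"Bland-Altman requires n >= 3 paired values, got {n}")
    mean_diff = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    se = sd / np.sqrt(n)
    tq = stats.t.ppf(0.975, n - 1)
    diff_ci = (mean_diff - tq * se, mean_diff + tq * se)
    if sd > 0:
        t_p = float(stats.ttest_1samp(d, 0.0).pvalue)
    else:
        t_p = 1.0 if mean_diff == 0 else 0.0
    loa = (mean_diff - 1.96 * sd, mean_diff + 1.96 * sd)
    avg = 0.5 * (df["line1_pct"] + df["luma_pct"]).to_numpy(dtype=float)
    if np.ptp(avg) == 0 or sd == 0:
        slope, slope_ci, slope_p = None, None, None
    else:
        res = stats.linregress(avg, d)
        tq2 = stats.t.ppf(0.975, n - 2)
        slope = float(res.slope)
        slope_ci = (slope - tq2 * res.stderr, slope + tq2 * res.stderr)
        slope_p = float(res.pvalue)
    return {
        "mean_diff": mean_diff,
        "diff_ci": diff_ci,
        "t_p": t_p,
        "loa": loa,
        "prop_slope": slope,
        "slope_ci": slope_ci,
        "slope_p": slope_p,
    }


def spearman_bootstrap(df: pd.DataFrame, n_boot: int = 1000,
                       seed: int | None = None) -> dict:
    """Spearman rho with percentile-bootstrap 95 % CI (resampling pairs)."""
    x = df["luma_pct"].to_numpy(dtype=float)
    y = df["line1_pct"].to_numpy(dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError(f"Spearman correlation requires n >= 3, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman rho undefined for a constant assay column")
    rho, p = stats.spearmanr(x, y)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            boots[b] = np.nan
            continue
        boots[b] = stats.spearmanr(xb, yb).statistic
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return {"spearman_rho": float(rho), "rho_ci": (float(lo), float(hi)), "rho_p": float(p)}


def paired_tests(df: pd.DataFrame, lilliefors: bool = True) -> dict:
    """Wilcoxon signed-rank on the pairs and KS normality of the differences.

    Wilcoxon uses the exact null distribution for n <= 25 (after dropping
    zero differences) and the normal approximation with continuity
    correction above.  The KS test assesses normality of d with parameters
    estimated from the data (Lilliefors correction by default).
    """
    d = _diffs(df)
    n = len(d)
    if n < 5:
        raise ValueError(f"paired tests require n >= 5, got {n}")
    nz = d[d != 0]
    if len(nz) == 0:
        wv, wp = np.nan, np.nan  # all differences zero: statistic undefined
    else:
        # exact null distribution for small n, else normal approximation
        # with continuity correction
        method = "exact" if len(nz) <= 25 else "approx"
        try:
            res = stats.wilcoxon(d, method=method, correction=True,
                                 zero_method="wilcox")
        except ValueError:  # ties prevent the exact distribution
            res = stats.wilcoxon(d, method="auto", correction=True,
                                 zero_method="wilcox")
        # report V as R reports it: the sum of ranks of positive differences
        ranks = stats.rankdata(np.abs(nz))
        wv, wp = float(np.sum(ranks[nz > 0])), float(res.pvalue)
    if np.std(d, ddof=1) == 0:
        ks_D, ks_p = np.nan, np.nan
    elif lilliefors:
        ks_D, ks_p = _lilliefors(d, dist="norm")
    else:
        ks_D, ks_p = stats.kstest(d, "norm", args=(np.mean(d), np.std(d, ddof=1)))
    return {"wilcoxon_V": wv, "wilcoxon_p": wp, "ks_D": float(ks_D), "ks_p": float(ks_p)}


def rm_anova(df: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Mixed ANOVA: assay (within) x data subset (between) + post hocs.

    Returns F and p for the between factor, the within factor and their
    interaction, plus Bonferroni-corrected (x number of subsets, capped at
    1) post-hoc Wilcoxon signed-rank p-values per subset.
    """
    import pingouin as pg  # deferred: pingouin is slow to import

    subsets = df["subset"].unique()
    if len(subsets) < 2:
        raise ValueError("rm-ANOVA needs at least 2 subsets")
    counts = df.groupby("subset").size()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"rm-ANOVA needs n >= 2 per subset; too small: {small}")
    long = pd.melt(df, id_vars=["sample_id", "subset"],
                   value_vars=["line1_pct", "luma_pct"],
                   var_name="assay", value_name="methylation")
    aov = pg.mixed_anova(data=long, dv="methylation", within="assay",
                         subject="sample_id", between="subset")
    aov = aov.set_index("Source")
    k = len(subsets)
    posthoc = {}
    for s in subsets:
        sub = df[df["subset"] == s]
        p = paired_tests(sub)["wilcoxon_p"] if len(sub) >= 5 else np.nan
        posthoc[s] = min(1.0, p * k) if np.isfinite(p) else np.nan
    return {
        "subset_F": float(aov.loc["subset", "F"]),
        "subset_p": float(aov.loc["subset", "p_unc"]),
        "assay_F": float(aov.loc["assay", "F"]),
        "assay_p": float(aov.loc["assay", "p_unc"]),
        "interaction_F": float(aov.loc["Interaction", "F"]),
        "interaction_p": float(aov.loc["Interaction", "p_unc"]),
        "posthoc_wilcoxon_bonferroni": posthoc,
        "alpha": alpha,
        "bonferroni_factor": k,
    }


def agreement_report(df: pd.DataFrame, subset: str | None = None,
                     n_boot: int = 1000, seed: int | None = None,
                     lilliefors: bool = True) -> AgreementReport:
    """Full per-subset agreement report (one table row per subset)."""
    if subset is not None:
        df = df[df["subset"] == subset]
    else:
        subset = str(df["subset"].iloc[0]) if df["subset"].nunique() == 1 else "all"
    line1 = df["line1_pct"].to_numpy(dtype=float)
    luma = df["luma_pct"].to_numpy(dtype=float)
    return AgreementReport(
        subset=subset,
        n=len(df),
        mean_line1=float(np.mean(line1)),
        sd_line1=float(np.std(line1, ddof=1)),
        mean_luma=float(np.mean(luma)),
        sd_luma=float(np.std(luma, ddof=1)),
        **paired_tests(df, lilliefors=lilliefors),
        **spearman_bootstrap(df, n_boot=n_boot, seed=seed),
        **bland_altman(df),
    )


def subset_reports(df: pd.DataFrame, n_boot: int = 1000,
                   seed: int | None = None) -> list[AgreementReport]:
    """One :class:`AgreementReport` per subset, in order of appearance."""
    seeds = np.random.SeedSequence(seed).generate_state(df["subset"].nunique())
    return [
        agreement_report(df, subset=s, n_boot=n_boot, seed=int(seeds[i]) % (2**31))
        for i, s in enumerate(dict.fromkeys(df["subset"]))
    ]
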