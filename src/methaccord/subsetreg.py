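"""Subset-specific linear model linking the two assays, with stepwise
likelihood-ratio model building and bootstrap confidence intervals.

Model
-----
For sample in subset s,

    LINE1 % = (theta1 + theta_Int,s) + (theta2 * theta_Slope,s) * LUMA % + eps,

with eps ~ N(0, sigma^2) shared across subsets.  theta_Int,s are additive
intercept offsets (neutral value 0) and theta_Slope,s multiplicative slope
factors (neutral value 1).  With a purely additive Gaussian residual the
maximum-likelihood fit is exactly the constrained least-squares fit, and

    -2LL = n * ln(2 pi sigma_hat^2) + n,    sigma_hat^2 = RSS / n.

Internally a model structure is represented as a partition of the subsets
into *intercept groups* (each group shares one intercept value, optionally
pinned at 0) and *slope groups* (each shares one slope value).  Every
partition is identifiable, which sidesteps the redundancy of the raw
(theta2, theta_Slope,s) product parametrization; the theta table of the
published parametrization is produced as a reporting view (when every
subset carries its own slope factor only the products are identified, and
theta2 is reported as 1).

Model building starts from the reduced model (one shared line), introduces
subset-specific intercepts then slopes in subset order, tests slope equality
ties, and finally tests pinning intercept groups at 0.  Each decision is a
likelihood-ratio test at alpha = 0.05: the extra parameter is retained only
if Delta(-2LL) = -2LL(full) - (-2LL(reduced)) is strictly below -3.84
(chi-square quantile, df = 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SubsetLinearSpec",
    "SubsetLinearFit",
    "fit_model",
    "lrt_step",
    "build_final_model",
    "bootstrap_ci",
    "LRT_CRITERION",
]

LRT_CRITERION = -3.84  # Delta(-2LL) threshold at alpha = 0.05, df = 1


class IdentifiabilityError(ValueError):
    pass


@dataclass(frozen=True)
class SubsetLinearSpec:
    """Structure of the subset-specific linear model.

    ``intercept_groups`` / ``slope_groups`` partition the subset labels;
    subsets in one group share the parameter value.  Intercept groups listed
    in ``zero_intercepts`` are pinned at 0 (not estimated).
    """

    subsets: tuple[str, ...]
    intercept_groups: tuple[tuple[str, ...], ...]
    slope_groups: tuple[tuple[str, ...], ...]
    zero_intercepts: tuple[tuple[str, ...], ...] = ()

    @classmethod
    def reduced(cls, subsets) -> "SubsetLinearSpec":
        """The reduced model: one shared intercept and slope (Occam start)."""
        subsets = tuple(subsets)
        return cls(subsets, (subsets,), (subsets,))

    @classmethod
    def from_free_mask(cls, subsets, free_intercepts=(), free_slopes=(),
                       slope_ties=()) -> "SubsetLinearSpec":
        """Build a spec from the free/fixed mask over the subset thetas.

        ``free_intercepts`` / ``free_slopes`` list subsets whose offset /
        factor is estimated; the rest stay at the neutral value (shared
        global line).  ``slope_ties`` lists pairs of free subsets whose
        slope factors are constrained equal.  Raises IdentifiabilityError
        when every subset is freed without a tie, since then the global
        parameter is redundant with the subset factors.
        """
        subsets = tuple(subsets)
        free_i, free_s = set(free_intercepts), set(free_slopes)
        if free_i == set(subsets):
            raise IdentifiabilityError(
                "all subset intercept offsets free together with the global "
                "intercept: values are identified only up to a shared constant"
            )
        if free_s == set(subsets) and not slope_ties:
            raise IdentifiabilityError(
                "all subset slope factors free together with the global slope: "
                "only the products theta2*theta_Slope,s are identified"
            )
        shared_i = tuple(s for s in subsets if s not in free_i)
        igroups = (shared_i,) + tuple((s,) for s in subsets if s in free_i)
        tied = {}
        for a, b in slope_ties:
            tied.setdefault(a, {a}).add(b)
        shared_s = tuple(s for s in subsets if s not in free_s)
        sgroups: list[tuple[str, ...]] = [shared_s] if shared_s else []
        seen: set[str] = set()
        for s in subsets:
            if s in free_s and s not in seen:
                grp = tuple(sorted(tied.get(s, {s}), key=subsets.index))
                seen.update(grp)
                sgroups.append(grp)
        return cls(subsets, igroups, tuple(sgroups))

    def n_params(self) -> int:
        free_igroups = [g for g in self.intercept_groups if g not in self.zero_intercepts]
        return len(free_igroups) + len(self.slope_groups)

    def describe(self) -> dict:
        return {
            "intercept_groups": [list(g) for g in self.intercept_groups],
            "zero_intercepts": [list(g) for g in self.zero_intercepts],
            "slope_groups": [list(g) for g in self.slope_groups],
        }


@dataclass
class SubsetLinearFit:
    """Constrained ML fit (= least squares) of one model structure."""

    spec: SubsetLinearSpec
    effective_intercepts: dict
    effective_slopes: dict
    sigma2: float
    minus2LL: float
    n: int
    se: dict = field(default_factory=dict)
    theta: dict = field(default_factory=dict)
    boot_ci: dict = field(default_factory=dict)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        a = df["subset"].map(self.effective_intercepts).to_numpy(dtype=float)
        b = df["subset"].map(self.effective_slopes).to_numpy(dtype=float)
        return a + b * df["luma_pct"].to_numpy(dtype=float)

    def to_dict(self) -> dict:
        return {
            "structure": self.spec.describe(),
            "effective_intercepts": self.effective_intercepts,
            "effective_slopes": self.effective_slopes,
            "sigma2": self.sigma2,
            "minus2LL": self.minus2LL,
            "n": self.n,
            "se": self.se,
            "theta": self.theta,
            "boot_ci": self.boot_ci,
        }


def _theta_table(spec: SubsetLinearSpec, intercepts: dict, slopes: dict) -> dict:
    """Report the fit in the published theta1..theta8 parametrization.

    theta1/theta2 are the intercept/slope of the first subset's groups when
    those groups anchor other subsets too; when every subset carries its own
    slope group, theta2 is reported as 1 and the factors equal the effective
    slopes (only the products are identified).
    """
    subsets = spec.subsets
    shared_i = next((g for g in spec.intercept_groups if len(g) > 1), None)
    theta1 = intercepts[shared_i[0]] if shared_i else 0.0
    shared_s = next((g for g in spec.slope_groups if len(g) > 1
                     and any(s not in g for s in subsets)), None)
    if shared_s is None and len(spec.slope_groups) == 1:
        shared_s = spec.slope_groups[0]
    theta2 = slopes[shared_s[0]] if shared_s else 1.0
    out = {"theta1": theta1, "theta2": theta2}
    for i, s in enumerate(subsets, start=3):
        out[f"theta{i}_Int_{s}"] = intercepts[s] - theta1
    for i, s in enumerate(subsets, start=len(subsets) + 3):
        out[f"theta{i}_Slope_{s}"] = slopes[s] / theta2 if theta2 != 0 else np.nan
    return out


def fit_model(df: pd.DataFrame, spec: SubsetLinearSpec) -> SubsetLinearFit:
    """Maximum-likelihood fit of one structure (exact, via least squares)."""
    sub = df["subset"].to_numpy()
    present = set(sub)
    missing = [s for s in spec.subsets if s not in present]
    if missing:
        raise ValueError(f"spec refers to subsets absent from the data: {missing}")
    counts = pd.Series(sub).value_counts()
    for g in spec.intercept_groups + spec.slope_groups:
        if len(g) == 1 and counts.get(g[0], 0) < 3:
            raise ValueError(f"subset {g[0]!r} has fewer than 3 samples for a free parameter")
    x = df["luma_pct"].to_numpy(dtype=float)
    y = df["line1_pct"].to_numpy(dtype=float)
    n = len(y)
    cols, names = [], []
    for g in spec.intercept_groups:
        if g in spec.zero_intercepts:
            continue
        cols.append(np.isin(sub, g).astype(float))
        names.append(("int", g))
    for g in spec.slope_groups:
        cols.append(np.isin(sub, g).astype(float) * x)
        names.append(("slope", g))
    X = np.column_stack(cols)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise IdentifiabilityError("design matrix is rank deficient for this spec")
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    minus2LL = n * np.log(2 * np.pi * sigma2) + n
    intercepts = {s: 0.0 for s in spec.subsets}
    slopes = {}
    se = {}
    # asymptotic SEs from the unbiased residual variance
    p = X.shape[1]
    s2_unb = rss / max(n - p, 1)
    cov = s2_unb * np.linalg.inv(X.T @ X)
    for (kind, g), b, v in zip(names, beta, np.diag(cov)):
        for s in g:
            if kind == "int":
                intercepts[s] = float(b)
            else:
                slopes[s] = float(b)
            se[f"{kind}_{s}"] = float(np.sqrt(v))
    return SubsetLinearFit(
        spec=spec,
        effective_intercepts=intercepts,
        effective_slopes=slopes,
        sigma2=sigma2,
        minus2LL=float(minus2LL),
        n=n,
        se=se,
        theta=_theta_table(spec, intercepts, slopes),
    )


def lrt_step(fit_full: SubsetLinearFit, fit_reduced: SubsetLinearFit,
             df: int = 1) -> tuple[bool, float, float]:
    """Likelihood-ratio decision between nested structures.

    Returns ``(keep_full, delta_m2ll, p)``.  The extra parameter(s) are
    retained iff Delta(-2LL) is strictly below -3.84 for df = 1 (the
    negative chi-square 0.95 quantile for other df).
    """
    if fit_full.spec.n_params() <= fit_reduced.spec.n_params():
        raise ValueError("fit_full must have more free parameters than fit_reduced")
    if fit_full.n != fit_reduced.n:
        raise ValueError("fits were obtained on different data")
    delta = fit_full.minus2LL - fit_reduced.minus2LL
    crit = LRT_CRITERION if df == 1 else -float(stats.chi2.ppf(0.95, df))
    p = float(stats.chi2.sf(max(-delta, 0.0), df))
    return delta < crit, float(delta), p


def _replace_groups(groups, old, new):
    out = [g for g in groups if g not in old]
    return tuple(out + list(new))


def build_final_model(df: pd.DataFrame, subset_order=None,
                      seed: int | None = None) -> tuple[SubsetLinearFit, list[dict]]:
    """Stepwise LRT model building from the reduced model; returns fit + log.

    Documented fixed order: (1) subset-specific intercepts in subset order,
    (2) subset-specific slopes in subset order, (3) slope equality ties in
    pair order, (4) intercept-to-zero tests in subset order.  Every step is
    recorded in the decision log.  The -2LL of the richer model never
    exceeds the nested model's (asserted), and the procedure is
    deterministic (``seed`` is accepted for interface symmetry only).
    """
    if subset_order is None:
        subset_order = list(dict.fromkeys(df["subset"]))
    subsets = tuple(subset_order)
    if len(subsets) < 2:
        raise ValueError("model building needs at least 2 subsets")
    spec = SubsetLinearSpec.reduced(subsets)
    fit = fit_model(df, spec)
    log: list[dict] = []

    def consider(candidate: SubsetLinearSpec, action: str, richer_is_candidate=True):
        nonlocal spec, fit
        cand_fit = fit_model(df, candidate)
        if richer_is_candidate:
            full, red = cand_fit, fit
        else:
            full, red = fit, cand_fit
        dof = abs(full.spec.n_params() - red.spec.n_params())
        assert full.minus2LL <= red.minus2LL + 1e-6, "nesting monotonicity violated"
        keep_full, delta, p = lrt_step(full, red, df=max(dof, 1))
        accept_candidate = keep_full if richer_is_candidate else not keep_full
        log.append({"action": action, "delta_m2ll": delta, "p": p,
                    "accepted": bool(accept_candidate),
                    "structure": candidate.describe()})
        if accept_candidate:
            spec, fit = candidate, cand_fit

    # (1) subset-specific intercepts
    for s in subsets:
        group = next(g for g in spec.intercept_groups if s in g)
        if len(group) == 1:
            continue
        rest = tuple(t for t in group if t != s)
        cand = SubsetLinearSpec(subsets,
                                _replace_groups(spec.intercept_groups, [group], [rest, (s,)]),
                                spec.slope_groups, spec.zero_intercepts)
        consider(cand, f"free intercept {s}")
    # (2) subset-specific slopes
    for s in subsets:
        group = next(g for g in spec.slope_groups if s in g)
        if len(group) == 1:
            continue
        rest = tuple(t for t in group if t != s)
        cand = SubsetLinearSpec(subsets, spec.intercept_groups,
                                _replace_groups(spec.slope_groups, [group], [rest, (s,)]),
                                spec.zero_intercepts)
        consider(cand, f"free slope {s}")
    # (3) slope equality ties (parsimony: merge unless the split is supported)
    for i in range(len(subsets)):
        for j in range(i + 1, len(subsets)):
            a, b = subsets[i], subsets[j]
            ga = next(g for g in spec.slope_groups if a in g)
            gb = next(g for g in spec.slope_groups if b in g)
            if ga == gb:
                continue
            merged = tuple(sorted(set(ga) | set(gb), key=subsets.index))
            cand = SubsetLinearSpec(subsets, spec.intercept_groups,
                                    _replace_groups(spec.slope_groups, [ga, gb], [merged]),
                                    spec.zero_intercepts)
            consider(cand, f"tie slopes {a}={b}", richer_is_candidate=False)
    # (4) intercept-to-zero tests (neutral value of a summand is 0)
    for g in list(spec.intercept_groups):
        if g in spec.zero_intercepts:
            continue
        cand = SubsetLinearSpec(subsets, spec.intercept_groups, spec.slope_groups,
                                spec.zero_intercepts + (g,))
        consider(cand, f"fix intercept {'+'.join(g)} = 0", richer_is_candidate=False)
    return fit, log


def bootstrap_ci(df: pd.DataFrame, spec: SubsetLinearSpec, n_boot: int = 1000,
                 seed: int | None = None, stratified: bool = True) -> SubsetLinearFit:
    """Percentile bootstrap CIs (2.5th/97.5th) for the final structure.

    Samples are resampled with replacement, stratified by subset (preserving
    the group sizes) unless ``stratified=False``.  Failed refits are redrawn
    and counted.  Returns the point fit with ``boot_ci`` filled for every
    effective intercept/slope and sigma2.
    """
    fit = fit_model(df, spec)
    rng = np.random.default_rng(seed)
    df = df.reset_index(drop=True)
    positions = {s: np.flatnonzero((df["subset"] == s).to_numpy())
                 for s in dict.fromkeys(df["subset"])}
    records: dict[str, list] = {}
    n_failed = 0
    b = 0
    while b < n_boot:
        if stratified:
            idx = np.concatenate([
                pos[rng.integers(0, len(pos), size=len(pos))]
                for pos in positions.values()
            ])
        else:
            idx = rng.integers(0, len(df), size=len(df))
        boot = df.iloc[idx].reset_index(drop=True)
        try:
            bf = fit_model(boot, spec)
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
            if n_failed > 10 * n_boot:
                raise RuntimeError("bootstrap: too many failed refits")
            continue
        for s, v in bf.effective_intercepts.items():
            records.setdefault(f"intercept_{s}", []).append(v)
        for s, v in bf.effective_slopes.items():
            records.setdefault(f"slope_{s}", []).append(v)
        records.setdefault("sigma2", []).append(bf.sigma2)
        b += 1
    if n_failed:
        logger.info("bootstrap_ci: %d failed refits redrawn", n_failed)
    fit.boot_ci = {
        k: tuple(np.percentile(v, [2.5, 97.5]).tolist()) for k, v in records.items()
    }
    return fit
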