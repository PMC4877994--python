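"""Pattern analysis of interassay differences.

The distribution of per-sample differences d = LINE-1 % - LUMA % is
summarized by a Pareto density estimate (PDE), modelled as a univariate
Gaussian mixture

    p(x) = sum_i  w_i N(x | mean_i, sd_i),     sum_i w_i = 1,

fitted by expectation-maximization followed by direct minimization of the
root-mean-square error between the mixture curve and the PDE curve (the fit
criterion used for selecting the number of components M).  Adjacent
components are separated by Bayes decision boundaries — the points where the
posterior membership probabilities of the two components are equal — which
partition the difference axis into M intervals.  Component membership is
then related to the originating tissue by a chi-square association test and
a decision tree on the tissue label (entropy impurity f(p) = -p ln p,
dichotomic splits), cross-validated by repeatedly leaving out a random tenth
of the samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

__all__ = [
    "PDEGrid",
    "MixtureModel",
    "TreeModel",
    "pde",
    "fit_gmm",
    "bayes_boundaries",
    "component_assignment",
    "association_chi2",
    "tissue_tree",
]

PARETO_PERCENTILE = 18.0   # Ultsch's heuristic for the Pareto radius
GRID_POINTS = 512


@dataclass
class PDEGrid:
    """Pareto density estimate on a regular grid (trapezoid integral = 1)."""

    x: np.ndarray
    density: np.ndarray
    radius: float


@dataclass
class MixtureModel:
    """Fitted Gaussian mixture over interassay differences (% methylation)."""

    M: int
    w: np.ndarray
    means: np.ndarray      # strictly increasing
    sds: np.ndarray
    rmse_to_pde: float
    boundaries: np.ndarray = field(default_factory=lambda: np.empty(0))
    #: RMSE per scanned component count, for audit
    scan_rmse: dict = field(default_factory=dict)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.sum(
            self.w[:, None] * stats.norm.pdf(x[None, :], self.means[:, None], self.sds[:, None]),
            axis=0,
        )

    def to_dict(self) -> dict:
        return {
            "M": self.M,
            "w": self.w.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "rmse_to_pde": self.rmse_to_pde,
            "boundaries": self.boundaries.tolist(),
            "scan_rmse": {int(k): float(v) for k, v in self.scan_rmse.items()},
        }


def pareto_radius(x: np.ndarray, max_pairs_n: int = 1000,
                  seed: int = 0) -> float:
    """Pareto radius: 18th percentile of the pairwise absolute differences.

    For n above ``max_pairs_n`` the pairwise set is computed on a seeded
    random subsample to keep the O(n^2) cost bounded.
    """
    x = np.asarray(x, dtype=float)
    if len(x) > max_pairs_n:
        rng = np.random.default_rng(seed)
        x = rng.choice(x, size=max_pairs_n, replace=False)
    d = np.abs(x[:, None] - x[None, :])
    iu = np.triu_indices(len(x), k=1)
    r = float(np.percentile(d[iu], PARETO_PERCENTILE))
    if r <= 0:
        raise ValueError("degenerate input: Pareto radius is zero")
    return r


def pde(differences: np.ndarray, radius: float | None = None) -> PDEGrid:
    """Pareto density estimation of a univariate sample.

    Uniform (ball) kernel of the Pareto radius evaluated on a regular
    512-point grid spanning the data range extended by 3 radii; the result
    is renormalized to trapezoid integral 1.
    """
    x = np.asarray(differences, dtype=float)
    if len(x) < 10:
        raise ValueError(f"PDE requires n >= 10, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: constant sample")
    r = pareto_radius(x) if radius is None else float(radius)
    grid = np.linspace(x.min() - 3 * r, x.max() + 3 * r, GRID_POINTS)
    counts = np.count_nonzero(np.abs(grid[:, None] - x[None, :]) <= r, axis=1)
    dens = counts / (len(x) * 2.0 * r)
    integral = np.trapezoid(dens, grid)
    return PDEGrid(x=grid, density=dens / integral, radius=r)


# ---------------------------------------------------------------------------
# Mixture fitting
# ---------------------------------------------------------------------------

def _em_fit(x: np.ndarray, M: int, seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """EM from k-means initialization; returns (w, means, sds).

    k-means starts place the component means according to the cluster
    structure of the sample.  (A quantile-based start was tried first; with a
    dominant cluster it seeds several components inside that cluster and EM
    then settles in a degenerate local optimum that splits it.)
    """
    x = x.reshape(-1, 1)
    sd_floor = 1e-3 * float(np.std(x))
    gm = GaussianMixture(
        n_components=M,
        covariance_type="full",
        init_params="kmeans",
        n_init=3,
        max_iter=200,
        tol=1e-8,
        reg_covar=sd_floor**2,
        random_state=seed,
    )
    import warnings
    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        # the tight tolerance rarely converges within max_iter; the RMSE
        # refinement that follows does not need a fully converged EM start
        warnings.simplefilter("ignore", ConvergenceWarning)
        gm.fit(x)
    w = gm.weights_.copy()
    means = gm.means_.ravel().copy()
    sds = np.sqrt(gm.covariances_.ravel())
    # prune components whose SD collapsed onto the floor with negligible mass
    keep = w > 1e-6
    if not keep.all():
        logger.warning("EM: pruned %d degenerate component(s) at M=%d", (~keep).sum(), M)
        w, means, sds = w[keep], means[keep], sds[keep]
        w = w / w.sum()
    return w, means, sds


def _pack(w, means, sds):
    # softmax weights, raw means, log sds -> unconstrained vector
    return np.concatenate([np.log(w), means, np.log(sds)])


def _unpack(theta, M):
    lw = theta[:M]
    w = np.exp(lw - lw.max())
    w = w / w.sum()
    means = theta[M:2 * M]
    sds = np.exp(theta[2 * M:])
    return w, means, sds


def _mixture_pdf(grid, w, means, sds, radius: float = 0.0):
    """Mixture density, optionally convolved with the PDE's uniform kernel.

    The PDE is the true density convolved with a uniform ball kernel of the
    Pareto radius; comparing the raw mixture to it would penalize sharp
    components for the kernel's own bias (and reward spuriously splitting
    them).  The RMSE criterion therefore smears the candidate mixture with
    the same kernel, which has the closed form
    (Phi((x - m + r)/s) - Phi((x - m - r)/s)) / (2 r) per component.
    """
    if radius > 0:
        comp = (stats.norm.cdf(grid[None, :], means[:, None] - radius, sds[:, None])
                - stats.norm.cdf(grid[None, :], means[:, None] + radius, sds[:, None])
                ) / (2.0 * radius)
        return np.sum(w[:, None] * comp, axis=0)
    return np.sum(w[:, None] * stats.norm.pdf(grid[None, :], means[:, None], sds[:, None]), axis=0)


def _rmse(theta, M, grid, target, radius):
    w, means, sds = _unpack(theta, M)
    return float(np.sqrt(np.mean((_mixture_pdf(grid, w, means, sds, radius) - target) ** 2)))


def fit_gmm(differences: np.ndarray, M_range=range(1, 6), seed: int = 0,
            pde_grid: PDEGrid | None = None) -> MixtureModel:
    """Fit the Gaussian mixture to the PDE of the differences.

    For each candidate M the mixture is initialized by EM (k-means start)
    and refined by direct minimization of the RMSE between the mixture curve
    and the PDE curve (convolved with the PDE's kernel; see _mixture_pdf).  The returned model is the most parsimonious M whose
    refined RMSE lies within ``RMSE_RELATIVE_TOL`` (relative) of the best
    across the scan.  Deterministic under ``seed``.
    """
    x = np.asarray(differences, dtype=float)
    M_range = list(M_range)
    if len(x) < 10 * max(M_range):
        raise ValueError(f"need n >= {10 * max(M_range)} samples for M up to {max(M_range)}")
    grid_obj = pde(x) if pde_grid is None else pde_grid
    grid, target = grid_obj.x, grid_obj.density
    fits: dict[int, tuple[float, tuple]] = {}
    for M in M_range:
        w, means, sds = _em_fit(x, M, seed)
        Meff = len(w)
        theta0 = _pack(w, means, sds)
        res = optimize.minimize(
            _rmse, theta0, args=(Meff, grid, target, grid_obj.radius),
            method="Nelder-Mead",
            options={"maxiter": 2000 * Meff, "xatol": 1e-6, "fatol": 1e-10},
        )
        w, means, sds = _unpack(res.x, Meff)
        fits[M] = (float(res.fun), (w, means, sds))
    # Parsimony against the PDE's own sampling error: adding components
    # reduces the RMSE indefinitely by tracking kernel-estimate wiggles, so
    # the scan stops at the smallest M whose residual is already at the
    # noise floor of the density estimate (RMS of the pointwise kernel
    # sampling SD).  If no candidate reaches the floor, the best RMSE wins.
    noise_floor = float(np.sqrt(np.mean(target / (2.0 * grid_obj.radius * len(x)))))
    adequate = [M for M in sorted(fits) if fits[M][0] <= noise_floor]
    chosen = adequate[0] if adequate else min(fits, key=lambda M: fits[M][0])
    rmse, (w, means, sds) = fits[chosen]
    order = np.argsort(means)
    model = MixtureModel(
        M=len(w), w=w[order], means=means[order], sds=sds[order],
        rmse_to_pde=rmse, scan_rmse={M: r for M, (r, _) in fits.items()},
    )
    model.boundaries = bayes_boundaries(model) if model.M >= 2 else np.empty(0)
    return model


def bayes_boundaries(model: MixtureModel) -> np.ndarray:
    """Decision points where adjacent components have equal posterior mass.

    For each adjacent pair the root of w_i N(x|m_i, s_i) = w_j N(x|m_j, s_j)
    between the two means is located numerically; if extreme weight
    imbalance leaves no root between the means, the boundary is taken at the
    changeover of the posterior argmax on a fine grid (with a warning).
    """
    if model.M < 2:
        raise ValueError("Bayes boundaries require M >= 2")
    bounds = []
    for i in range(model.M - 1):
        wi, mi, si = model.w[i], model.means[i], model.sds[i]
        wj, mj, sj = model.w[i + 1], model.means[i + 1], model.sds[i + 1]

        def f(x):
            return (np.log(wi) + stats.norm.logpdf(x, mi, si)
                    - np.log(wj) - stats.norm.logpdf(x, mj, sj))

        lo, hi = mi, mj
        if f(lo) > 0 and f(hi) < 0:
            bounds.append(float(optimize.brentq(f, lo, hi, xtol=1e-12)))
        else:
            logger.warning(
                "bayes_boundaries: no root between means %d and %d; using grid changeover",
                i, i + 1,
            )
            grid = np.linspace(mi - 4 * si, mj + 4 * sj, 20001)
            post = np.vstack([
                np.log(model.w[k]) + stats.norm.logpdf(grid, model.means[k], model.sds[k])
                for k in (i, i + 1)
            ])
            win = np.argmax(post, axis=0)
            change = np.nonzero(np.diff(win))[0]
            if len(change) == 0:  # one component dominates the whole stripe
                bounds.append(float(0.5 * (mi + mj)))
            else:
                bounds.append(float(0.5 * (grid[change[0]] + grid[change[0] + 1])))
    return np.array(bounds)


def component_assignment(differences: np.ndarray, model: MixtureModel):
    """Posterior over components per point and hard argmax labels.

    Returns ``(labels, posterior)`` with posterior rows summing to one.
    """
    x = np.asarray(differences, dtype=float)
    logp = (np.log(model.w)[None, :]
            + stats.norm.logpdf(x[:, None], model.means[None, :], model.sds[None, :]))
    logp -= logp.max(axis=1, keepdims=True)
    post = np.exp(logp)
    post /= post.sum(axis=1, keepdims=True)
    return np.argmax(post, axis=1), post


def association_chi2(labels, components) -> dict:
    """Pearson chi-square of tissue label x mixture component.

    Empty rows/columns are dropped with a warning; df = (r-1)(c-1) of the
    resulting table.
    """
    import pandas as pd

    table = pd.crosstab(pd.Series(labels, name="tissue"),
                        pd.Series(components, name="component"))
    before = table.shape
    table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    if table.shape != before:
        logger.warning("association_chi2: dropped empty rows/columns %s -> %s",
                       before, table.shape)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table needs at least 2 rows and 2 columns")
    chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return {"chi2": float(chi2), "df": int(dof), "p": float(p),
            "table": table}


# ---------------------------------------------------------------------------
# Decision tree on the categorical tissue label
# ---------------------------------------------------------------------------

def _info(counts: np.ndarray) -> float:
    """Total information index of a node: sum of f(p) = -p ln p."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


@dataclass
class _Node:
    left_tissues: frozenset | None = None   # None => leaf
    left: "_Node | None" = None
    right: "_Node | None" = None
    class_counts: np.ndarray | None = None

    def predict(self, tissue) -> int:
        if self.left_tissues is None:
            return int(np.argmax(self.class_counts))
        child = self.left if tissue in self.left_tissues else self.right
        return child.predict(tissue)

    def describe(self, classes) -> dict:
        props = (self.class_counts / self.class_counts.sum()).tolist()
        if self.left_tissues is None:
            return {"leaf": True, "class_props": props,
                    "majority": int(classes[int(np.argmax(self.class_counts))])}
        return {
            "leaf": False,
            "class_props": props,
            "split": sorted(self.left_tissues),
            "left": self.left.describe(classes),
            "right": self.right.describe(classes),
        }


@dataclass
class TreeModel:
    """Tissue -> mixture-component decision tree with CV accuracy."""

    splits: dict
    leaf_class_props: list
    cv_accuracy: float
    classes: np.ndarray
    root: _Node

    def predict(self, tissues) -> np.ndarray:
        return np.array([self.classes[self.root.predict(t)] for t in tissues])

    def to_dict(self) -> dict:
        return {"splits": self.splits, "leaf_class_props": self.leaf_class_props,
                "cv_accuracy": self.cv_accuracy}


def _grow(tissues: np.ndarray, y_idx: np.ndarray, n_classes: int) -> _Node:
    counts = np.bincount(y_idx, minlength=n_classes)
    node = _Node(class_counts=counts.astype(float))
    uniq = sorted(set(tissues))
    if len(uniq) < 2 or (counts > 0).sum() < 2:
        return node
    parent_info = _info(counts)
    best_gain, best_split = 0.0, None
    # dichotomic splits: enumerate proper subsets (up to complements)
    for mask in range(1, 2 ** (len(uniq) - 1)):
        left_set = frozenset(t for b, t in enumerate(uniq) if mask >> b & 1)
        sel = np.isin(tissues, list(left_set))
        li = _info(np.bincount(y_idx[sel], minlength=n_classes))
        ri = _info(np.bincount(y_idx[~sel], minlength=n_classes))
        frac = sel.mean()
        gain = parent_info - (frac * li + (1 - frac) * ri)
        if gain > best_gain + 1e-12:
            best_gain, best_split = gain, (left_set, sel)
    if best_split is None:
        return node
    left_set, sel = best_split
    node.left_tissues = left_set
    node.left = _grow(tissues[sel], y_idx[sel], n_classes)
    node.right = _grow(tissues[~sel], y_idx[~sel], n_classes)
    return node


def tissue_tree(labels, components, k_frac: float = 0.1, n_rep: int = 100,
                seed: int = 0) -> TreeModel:
    """Decision tree predicting mixture component from the tissue label.

    The tree splits the categorical tissue label dichotomically using the
    information index f(p) = -p ln p; the predicted component of a leaf is
    its majority class.  Cross-validation repeatedly (``n_rep`` times) holds
    out a randomly picked ``k_frac`` of the samples (k = ceil(n * k_frac),
    drawn without replacement), rebuilds the tree on the remainder and
    scores the held-out accuracy; ``cv_accuracy`` is the mean.
    """
    tissues = np.asarray(labels)
    comps = np.asarray(components)
    if len(set(tissues)) < 2 or len(set(comps)) < 2:
        raise ValueError("need at least 2 tissues and 2 components")
    t_counts = {t: int((tissues == t).sum()) for t in set(tissues)}
    small = [t for t, c in t_counts.items() if c < 2]
    if small:
        logger.warning("tissue_tree: tissues with fewer than 2 samples kept: %s", small)
    classes, y_idx = np.unique(comps, return_inverse=True)
    root = _grow(tissues, y_idx, len(classes))
    rng = np.random.default_rng(seed)
    n = len(tissues)
    k = int(np.ceil(n * k_frac))
    accs = np.empty(n_rep)
    for rep in range(n_rep):
        held = rng.choice(n, size=k, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[held] = True
        sub = _grow(tissues[~mask], y_idx[~mask], len(classes))
        pred = np.array([sub.predict(t) for t in tissues[mask]])
        accs[rep] = float(np.mean(pred == y_idx[mask]))
    desc = root.describe(classes)

    def _leaves(d):
        if d.get("leaf"):
            return [d["class_props"]]
        return _leaves(d["left"]) + _leaves(d["right"])

    return TreeModel(splits=desc, leaf_class_props=_leaves(desc),
                     cv_accuracy=float(np.mean(accs)), classes=classes, root=root)
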