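"""Diagnostic figures: Bland-Altman plot and PDE/GMM overlay."""

from __future__ import annotations

import numpy as np

from .agreement import bland_altman
from .mixpattern import MixtureModel, PDEGrid


def bland_altman_plot(df, ax=None):
    """Difference-vs-mean plot with bias line and limits of agreement."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    stats = bland_altman(df)
    avg = 0.5 * (df["line1_pct"] + df["luma_pct"])
    d = df["line1_pct"] - df["luma_pct"]
    ax.scatter(avg, d, s=12, alpha=0.7)
    ax.axhline(0, color="magenta")
    ax.axhline(stats["mean_diff"], color="tab:blue")
    for limit in stats["loa"]:
        ax.axhline(limit, color="red", linestyle="--")
    ax.set_xlabel("mean of LINE-1 and LUMA (% methylation)")
    ax.set_ylabel("LINE-1 - LUMA (% methylation)")
    return ax


def pde_gmm_plot(grid: PDEGrid, model: MixtureModel, ax=None):
    """Pareto density estimate with the fitted mixture and Bayes boundaries."""
    import matplotlib.pyplot as plt
    from scipy import stats as sps

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(grid.x, grid.density, "k-", label="PDE")
    ax.plot(grid.x, model.pdf(grid.x), "r-", label=f"GMM (M={model.M})")
    for w, m, s in zip(model.w, model.means, model.sds):
        ax.plot(grid.x, w * sps.norm.pdf(grid.x, m, s), "b:", lw=1)
    for b in np.atleast_1d(model.boundaries):
        ax.axvline(b, color="magenta", lw=1)
    ax.set_xlabel("LINE-1 - LUMA (% methylation)")
    ax.set_ylabel("density")
    ax.legend()
    return ax
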