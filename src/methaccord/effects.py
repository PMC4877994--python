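"""Cross-assay treatment effect sizes (Cohen's d) within the cell lines.

Every unordered pair of treatment conditions within a cell line yields a
standardized mean difference under each assay; comparing the two resulting
effect-size profiles (and their rank correlation) probes whether the assays
report *changes* in methylation consistently even where their absolute
levels disagree.  Solvent controls (DMSO) are pooled with the untreated
condition by default, so the published exposure plan yields C(12, 2) = 66
pairs for MCF7.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["EffectSizeRecord", "cohens_d", "pairwise_effects"]

#: conditions pooled into a single control group by default
DEFAULT_MERGE = {"DMSO": "Control", "Untreated": "Control"}


@dataclass
class EffectSizeRecord:
    cell_line: str
    condition_a: str
    condition_b: str
    n_a: int
    n_b: int
    d_line1: float
    d_luma: float

    def to_dict(self):
        return asdict(self)


def cohens_d(group_a, group_b, hedges: bool = False) -> float:
    """Cohen's d = (mean_a - mean_b) / pooled SD.

    Pooled SD uses the n-1 weighting
    s_p = sqrt(((n_a - 1) s_a^2 + (n_b - 1) s_b^2) / (n_a + n_b - 2)).
    ``hedges=True`` applies the small-sample correction factor
    1 - 3 / (4 (n_a + n_b) - 9); the plain statistic is the default.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("Cohen's d requires at least 2 observations per group")
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise ValueError("zero pooled standard deviation")
    d = (np.mean(a) - np.mean(b)) / np.sqrt(sp2)
    if hedges:
        d *= 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)
    return float(d)


def pairwise_effects(df: pd.DataFrame, merge_map: dict | None = None,
                     cell_lines=None, restrict_pairs: dict | None = None,
                     hedges: bool = False):
    """All pairwise treatment effect sizes per cell line, under both assays.

    Parameters
    ----------
    df
        Sample sheet with ``treatment`` labels.
    merge_map
        Condition relabelling applied first (default pools DMSO with the
        untreated condition into ``Control``).
    cell_lines
        Subsets to analyse (default: all with >= 2 post-merge conditions).
    restrict_pairs
        Optional ``{cell_line: [(cond_a, cond_b), ...]}`` restricting the
        comparison set of a cell line (the published comparison count for
        SHSY5Y is smaller than all pairs; the selection is not stated, so it
        is exposed as configuration rather than guessed).

    Returns ``(records, rho, p)``: the effect-size records and the Spearman
    correlation between the two assays' effect-size vectors.
    """
    merge_map = DEFAULT_MERGE if merge_map is None else merge_map
    df = df.copy()
    df["treatment"] = df["treatment"].replace(merge_map)
    if cell_lines is None:
        k = df.groupby("subset")["treatment"].nunique()
        cell_lines = [s for s in k.index if k[s] >= 2]
    records: list[EffectSizeRecord] = []
    for cl in cell_lines:
        sub = df[df["subset"] == cl]
        conditions = list(dict.fromkeys(sub["treatment"]))
        pairs = (restrict_pairs or {}).get(cl) or list(combinations(conditions, 2))
        for ca, cb in pairs:
            ga = sub[sub["treatment"] == ca]
            gb = sub[sub["treatment"] == cb]
            if len(ga) < 2 or len(gb) < 2:
                logger.warning("pairwise_effects: skipping %s %s vs %s (group too small)",
                               cl, ca, cb)
                continue
            records.append(EffectSizeRecord(
                cell_line=cl, condition_a=ca, condition_b=cb,
                n_a=len(ga), n_b=len(gb),
                d_line1=cohens_d(ga["line1_pct"], gb["line1_pct"], hedges=hedges),
                d_luma=cohens_d(ga["luma_pct"], gb["luma_pct"], hedges=hedges),
            ))
    if len(records) >= 3:
        d1 = [r.d_line1 for r in records]
        d2 = [r.d_luma for r in records]
        rho, p = stats.spearmanr(d1, d2)
    else:
        rho, p = np.nan, np.nan
    return records, float(rho), float(p)
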