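"""Group-comparison statistics for pipeline outputs.

Paired t tests for two-group comparisons, one- or two-way ANOVA with a
Bonferroni post hoc for three or more groups, and the usual significance
tiers (*, **, *** at p < 0.05, 0.01, 0.001).  Two-way ANOVA is restricted to
balanced layouts (zone x treatment designs are balanced), which sidesteps
the choice among sum-of-squares types.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols

from . import defaults

log = logging.getLogger(__name__)


def significance_tier(p: float, tiers=defaults.SIGNIFICANCE_TIERS) -> str:
    """'ns', '*', '**' or '***' for the conventional p-value cut-offs."""
    t1, t2, t3 = tiers
    if p < t3:
        return "***"
    if p < t2:
        return "**"
    if p < t1:
        return "*"
    return "ns"


@dataclass
class ComparisonResult:
    """Outcome of a group comparison with optional post hoc table."""

    test: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    tier: str
    posthoc: pd.DataFrame | None = field(default=None, repr=False)
    extra: dict = field(default_factory=dict, repr=False)


def paired_t_test(x, y) -> ComparisonResult:
    """Paired t test on the differences x - y.

    Degenerate cases follow a logged convention: all-zero differences give
    t = 0, p = 1; zero-variance non-zero differences give p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    sd = d.std(ddof=1)
    n = d.size
    if sd == 0:
        if d.mean() == 0:
            log.warning("paired t: all differences zero; reporting t=0, p=1")
            t, p = 0.0, 1.0
        else:
            log.warning("paired t: zero-variance non-zero differences; p -> 0")
            t = np.inf if d.mean() > 0 else -np.inf
            p = 0.0
    else:
        t = float(d.mean() / (sd / np.sqrt(n)))
        p = float(2 * sps.t.sf(abs(t), df=n - 1))
    return ComparisonResult(
        test="paired_t", statistic=float(t), df=(n - 1,), p_value=p,
        tier=significance_tier(p),
    )


def _bonferroni_pairs(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    names = list(groups)
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        t, p = sps.ttest_ind(groups[a], groups[b])
        p_adj = min(1.0, float(p) * m)
        rows.append(
            {"group_a": a, "group_b": b, "t": float(t), "p_raw": float(p),
             "p_bonferroni": p_adj, "tier": significance_tier(p_adj)}
        )
    return pd.DataFrame(rows)


def one_way_anova(groups: dict[str, np.ndarray]) -> ComparisonResult:
    """One-way ANOVA with Bonferroni-adjusted pairwise t tests."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(a.size < 2 for a in arrays.values()):
        raise ValueError("each group needs n >= 2")
    f, p = sps.f_oneway(*arrays.values())
    if np.isnan(f):  # all groups identical constants
        f, p = 0.0, 1.0
    k = len(arrays)
    n = sum(a.size for a in arrays.values())
    posthoc = _bonferroni_pairs(arrays)
    return ComparisonResult(
        test="one_way_anova", statistic=float(f), df=(k - 1, n - k),
        p_value=float(p), tier=significance_tier(float(p)), posthoc=posthoc,
    )


def two_way_anova(table: pd.DataFrame, value: str, factor_a: str, factor_b: str) -> ComparisonResult:
    """Two-way ANOVA with interaction on a balanced layout.

    ``table`` is long-format with one row per observation.  Raises on
    unbalanced designs (every factor-level combination must have the same
    number of replicates >= 2).
    """
    counts = table.groupby([factor_a, factor_b])[value].count()
    n_a = table[factor_a].nunique()
    n_b = table[factor_b].nunique()
    if len(counts) != n_a * n_b or counts.nunique() != 1:
        raise ValueError("two-way ANOVA requires a complete balanced layout")
    if counts.iloc[0] < 2:
        raise ValueError("need >= 2 replicates per cell")
    model = ols(
        f"{value} ~ C({factor_a}) * C({factor_b})", data=table
    ).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    inter = f"C({factor_a}):C({factor_b})"
    p_inter = float(anova.loc[inter, "PR(>F)"])
    # Bonferroni pairwise on factor_a within each level of factor_b
    rows = []
    levels_b = sorted(table[factor_b].unique())
    pairs = [
        (b, a1, a2)
        for b in levels_b
        for a1, a2 in itertools.combinations(sorted(table[factor_a].unique()), 2)
    ]
    m = len(pairs)
    for b, a1, a2 in pairs:
        g1 = table.loc[(table[factor_a] == a1) & (table[factor_b] == b), value]
        g2 = table.loc[(table[factor_a] == a2) & (table[factor_b] == b), value]
        t, p = sps.ttest_ind(g1, g2)
        p_adj = min(1.0, float(p) * m)
        rows.append(
            {"level_b": b, "group_a": a1, "group_b": a2, "t": float(t),
             "p_raw": float(p), "p_bonferroni": p_adj,
             "tier": significance_tier(p_adj)}
        )
    return ComparisonResult(
        test="two_way_anova",
        statistic=float(anova.loc[inter, "F"]),
        df=(float(anova.loc[inter, "df"]), float(anova.loc["Residual", "df"])),
        p_value=p_inter,
        tier=significance_tier(p_inter),
        posthoc=pd.DataFrame(rows),
        extra={"anova_table": anova},
    )


def anova_bonferroni(data, **kwargs) -> ComparisonResult:
    """Dispatch: dict of 1-D arrays -> one-way; DataFrame + factors -> two-way."""
    if isinstance(data, dict):
        return one_way_anova(data)
    return two_way_anova(data, **kwargs)
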