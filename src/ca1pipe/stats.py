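"""Group-level statistics: repeated-measures ANOVA across behavioral states,
t-tests, chi-square proportion tests and two-sample Kolmogorov-Smirnov tests.

Animal is the unit of analysis except for aberrant-activity proportions,
where cells are pooled across animals (and flagged as such). Post-hoc
pairwise comparisons are reported unadjusted (the convention in this
literature) alongside Holm-adjusted values.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .containers import GroupResult

__all__ = ["rm_anova_states", "two_sample_test", "proportion_chi2",
           "ks_compare"]


def _mean_sem(x: np.ndarray):
    x = np.asarray(x, dtype=float)
    return float(np.mean(x)), float(np.std(x, ddof=1) / np.sqrt(len(x)))


def rm_anova_states(table: pd.DataFrame) -> GroupResult:
    """One-way repeated-measures ANOVA over conditions (columns) within
    subjects (rows), sphericity assumed, followed by pairwise paired t-tests.

    Incomplete subjects are dropped with a warning. Post-hoc p values are
    unadjusted; Holm-adjusted values ride along in `effect_summary`.
    """
    import warnings

    import pingouin as pg
    from statsmodels.stats.multitest import multipletests

    if table.shape[1] < 2:
        raise ValueError("need >= 2 conditions")
    complete = table.dropna(axis=0)
    if len(complete) < len(table):
        warnings.warn(f"dropped {len(table) - len(complete)} incomplete subjects")
    if len(complete) < 3:
        raise ValueError("need >= 3 complete subjects")
    n, k_cond = complete.shape
    df1, df2 = k_cond - 1, (n - 1) * (k_cond - 1)
    x = complete.to_numpy()
    ss_cond = n * ((x.mean(axis=0) - x.mean()) ** 2).sum()
    if ss_cond <= 1e-12 * max(x.var(), 1.0):
        # no condition effect at all: pingouin's table degenerates
        F, p = 0.0, 1.0
    else:
        long = complete.reset_index(names="subject").melt(
            id_vars="subject", var_name="condition", value_name="value")
        aov = pg.rm_anova(data=long, dv="value", within="condition",
                          subject="subject", correction=False, detailed=True)
        row = aov.iloc[0]
        F, p = float(row["F"]), float(row["p_unc"])
        df1 = int(row["DF"])
        df2 = int(aov.iloc[1]["DF"])

    conds = list(complete.columns)
    post, raw_p = [], []
    for i in range(len(conds)):
        for j in range(i + 1, len(conds)):
            t = sstats.ttest_rel(complete[conds[i]], complete[conds[j]])
            post.append((f"{conds[i]} vs {conds[j]}", float(t.pvalue)))
            raw_p.append(float(t.pvalue))
    holm = multipletests(raw_p, method="holm")[1] if raw_p else []
    effect = {c: _mean_sem(complete[c].to_numpy()) for c in conds}
    effect["post_hoc_holm"] = [
        (name, float(ph)) for (name, _), ph in zip(post, holm)]
    return GroupResult(test_name="rm_anova", statistic=F, df=(df1, df2),
                       p_value=p, post_hoc=post, effect_summary=effect)


def two_sample_test(a: Sequence[float], b: Sequence[float],
                    paired: bool = False,
                    alternative: str = "two-sided") -> GroupResult:
    """Student's t-test (paired or independent), 1- or 2-sided.

    df = n_a + n_b - 2 unpaired, n - 1 paired. A zero-variance comparison
    is an error (degenerate t)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per sample")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal n")
        diffs = a - b
        if np.allclose(diffs.std(ddof=1), 0) and not np.allclose(diffs, 0):
            raise ValueError("zero-variance paired differences: t degenerate")
        res = sstats.ttest_rel(a, b, alternative=alternative)
        df = (len(a) - 1,)
    else:
        if np.allclose(a.std(ddof=1), 0) and np.allclose(b.std(ddof=1), 0):
            raise ValueError("zero pooled variance: t undefined")
        res = sstats.ttest_ind(a, b, alternative=alternative)
        df = (len(a) + len(b) - 2,)
    name = ("paired" if paired else "two-sample") + f" t ({alternative})"
    return GroupResult(
        test_name=name, statistic=float(res.statistic), df=df,
        p_value=float(res.pvalue),
        effect_summary={"a": _mean_sem(a), "b": _mean_sem(b)})


def proportion_chi2(table) -> GroupResult:
    """Pearson chi-square on a 2x2 contingency table, no continuity
    correction, df = 1."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table < 0):
        raise ValueError("negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("all marginals must be > 0")
    chi2, p, dof, _ = sstats.chi2_contingency(table, correction=False)
    return GroupResult(test_name="chi2", statistic=float(chi2), df=(int(dof),),
                       p_value=float(p))


def ks_compare(a: Sequence[float], b: Sequence[float]) -> GroupResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("need n >= 5 per sample")
    res = sstats.ks_2samp(a, b, method="asymp")
    return GroupResult(test_name="ks_2samp", statistic=float(res.statistic),
                       df=(len(a), len(b)), p_value=float(res.pvalue))
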