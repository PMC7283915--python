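"""Treatment-comparison layer: one-sample t against a constant, one-way
ANOVA with Tukey HSD and compact letter display, and Pearson correlation.

Testing an index such as the LER "against 1" is implemented as a one-sample
t test of the replicate indices against the constant (a constant has no
variance, so the Welch two-sample framing reduces to the one-sample test).
Degenerate inputs (too few replicates, zero variance) yield flagged results
rather than numbers.
"""

from __future__ import annotations

import itertools
import string
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

FLAG_TOO_FEW = "too_few_values"
FLAG_ZERO_VARIANCE = "zero_variance"
FLAG_DEGENERATE = "degenerate"


@dataclass(frozen=True)
class TestResult:
    """A single hypothesis-test outcome."""

    method: str
    estimate: float
    statistic: float
    df: float
    p_value: float
    reference: float | None = None
    flag: str | None = None


@dataclass(frozen=True)
class TukeyGrouping:
    """Tukey HSD outcome: level means, pairwise p values, and letters.

    Levels sharing a letter are not significantly different at ``alpha``.
    """

    level_means: dict
    letters: dict
    alpha: float
    pairwise_p: dict = field(default_factory=dict)


def welch_vs_ref(values, reference: float = 0.0) -> TestResult:
    """Two-sided one-sample t test of replicate values against a constant."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    if n < 2:
        return TestResult("one_sample_t", float(v.mean()) if n else np.nan,
                          np.nan, np.nan, np.nan, reference, FLAG_TOO_FEW)
    mean = float(v.mean())
    if np.ptp(v) == 0.0:
        if mean == reference:
            # all replicates exactly on the reference: trivially null
            return TestResult("one_sample_t", mean, 0.0, n - 1, 1.0,
                              reference, FLAG_ZERO_VARIANCE)
        return TestResult("one_sample_t", mean, np.nan, n - 1, np.nan,
                          reference, FLAG_ZERO_VARIANCE)
    res = sps.ttest_1samp(v, reference)
    return TestResult("one_sample_t", mean, float(res.statistic),
                      float(n - 1), float(res.pvalue), reference)


def pearson(x, y) -> TestResult:
    """Pearson correlation with the t-based two-sided p on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    n = x.size
    if n < 3:
        return TestResult("pearson", np.nan, np.nan, np.nan, np.nan, flag=FLAG_TOO_FEW)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        return TestResult("pearson", np.nan, np.nan, np.nan, np.nan, flag=FLAG_DEGENERATE)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return TestResult("pearson", np.nan, np.nan, np.nan, np.nan,
                          flag=FLAG_ZERO_VARIANCE)
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    t = r * np.sqrt((n - 2) / max(1.0 - r * r, np.finfo(float).tiny))
    return TestResult("pearson", r, float(t), float(n - 2), float(res.pvalue))


def _compact_letter_display(labels, means, significant_pairs, max_levels=12):
    """Compact letter display from the non-significance graph.

    Enumerates the maximal cliques of the graph whose edges connect levels
    that are NOT significantly different, orders them by their best member's
    mean (ties broken alphabetically by level label), and assigns one letter
    per clique.  Exact for the small level counts of designed experiments.
    """
    k = len(labels)
    if k > max_levels:
        raise ValueError(f"compact letter display supports up to {max_levels} levels")
    order = sorted(labels, key=lambda l: (-means[l], l))
    sig = {frozenset(p) for p in significant_pairs}

    def is_clique(subset):
        return all(frozenset(p) not in sig for p in itertools.combinations(subset, 2))

    cliques: list[tuple] = []
    for size in range(k, 0, -1):
        for subset in itertools.combinations(order, size):
            if is_clique(subset) and not any(set(subset) <= set(c) for c in cliques):
                cliques.append(subset)
    # order cliques by the position of their best-ranked member, then labels
    cliques.sort(key=lambda c: (min(order.index(l) for l in c), c))
    letters = {l: "" for l in labels}
    for letter, clique in zip(string.ascii_lowercase, cliques):
        for l in clique:
            letters[l] += letter
    return {l: "".join(sorted(s)) for l, s in letters.items()}


def oneway_tukey(values_by_level, alpha: float = 0.05, tukey: bool = True):
    """One-way ANOVA plus all-pairwise Tukey HSD with letter display.

    Parameters
    ----------
    values_by_level:
        Mapping of level label to its replicate series.  Levels with fewer
        than two finite replicates are excluded with a warning.
    alpha:
        Family-wise significance level for the letter display.
    tukey:
        When False, skip the pairwise stage (the studentized-range
        quadrature dominates the runtime) and return ``None`` as the
        grouping; useful for omnibus-only simulation loops.

    Returns
    -------
    (TestResult, TukeyGrouping | None)
        The omnibus F test and the pairwise grouping.  All-identical data
        yields a flagged-undefined F and a single shared letter.
    """
    clean: dict = {}
    for label, vals in values_by_level.items():
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        if v.size < 2:
            warnings.warn(f"level {label!r} excluded: fewer than 2 replicates",
                          stacklevel=2)
            continue
        clean[label] = v
    if len(clean) < 2:
        raise ValueError("one-way ANOVA needs at least 2 levels with >= 2 replicates")

    labels = sorted(clean)
    groups = [clean[l] for l in labels]
    n_total = sum(g.size for g in groups)
    df_between = len(groups) - 1
    df_within = n_total - len(groups)
    means = {l: float(clean[l].mean()) for l in labels}

    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0.0:
        anova = TestResult("oneway_anova", float(pooled.mean()), np.nan,
                           float(df_between), np.nan, flag=FLAG_DEGENERATE)
        letters = {l: "a" for l in labels}
        return anova, TukeyGrouping(means, letters, alpha)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_res = sps.f_oneway(*groups)

    anova = TestResult("oneway_anova", float(np.mean([g.mean() for g in groups])),
                       float(f_res.statistic), float(df_between), float(f_res.pvalue))
    if not tukey:
        return anova, None

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tukey_res = sps.tukey_hsd(*groups)

    pairwise_p = {}
    significant = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        p = float(tukey_res.pvalue[i, j])
        pairwise_p[(labels[i], labels[j])] = p
        if np.isfinite(p) and p < alpha:
            significant.append((labels[i], labels[j]))
    letters = _compact_letter_display(labels, means, significant)
    return anova, TukeyGrouping(means, letters, alpha, pairwise_p)
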