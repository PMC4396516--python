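"""The study's statistical layer.

Pearson correlation with its analytic two-tailed p (and the r,n -> p
transform used to verify printed correlation results), Student's independent
t-test from raw data or from printed summary cells (mean +/- sd, n), 2x2
chi-square without continuity correction, one-way ANOVA with Levene's
homogeneity test gating Games-Howell vs Bonferroni post hocs, and seeded
permutation oracles for calibration checks.

Everything is two-tailed.  Standard tests are delegated to scipy.stats; the
Games-Howell procedure (Welch-type pairwise t with Welch-Satterthwaite df
referenced to the studentized-range distribution) and the r,n -> p transform
are implemented here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .simulate import ValidationError


@dataclass
class StatResult:
    statistic_name: str
    statistic_value: float
    df: tuple[float, ...]
    p_two_tailed: float
    method_notes: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_two_tailed <= 1.0 or np.isnan(self.p_two_tailed)):
            raise ValidationError("p must lie in [0, 1]")


@dataclass(frozen=True)
class SummaryGroup:
    """A printed table cell: mean +/- sd with group size n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")
        if self.n < 2:
            raise ValidationError("n must be >= 2")


def pearson_r_p(x, y) -> StatResult:
    """Sample Pearson r with the analytic two-tailed p.

    p comes from t = r sqrt(n-2)/sqrt(1-r^2) on n-2 df, equivalent to
    scipy's exact-beta formulation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("x and y must have equal length n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return StatResult("pearson_r", float(r), (float(x.size - 2),), float(p),
                      method_notes=f"n={x.size}, two-tailed t on n-2 df")


def p_from_r_n(r: float, n: int) -> float:
    """Two-tailed p for a given correlation coefficient and sample size.

    The verification path for printed (r, p) pairs: t = r sqrt(n-2) /
    sqrt(1-r^2), referred to the t distribution with n-2 df.  |r| >= 1
    returns p = 0 (a boundary case, not an estimate).
    """
    if n < 3:
        raise ValidationError("n must be >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(t, n - 2))


def ttest_independent(a, b, mode: str = "pooled") -> StatResult:
    """Student's independent two-sample t (pooled variance by default).

    The pooled form with df = n1+n2-2 is the study's convention; ``mode=
    'welch'`` gives the unequal-variance variant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs n >= 2")
    equal_var = mode == "pooled"
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = a.size + b.size - 2 if equal_var else _welch_df(
        a.var(ddof=1), a.size, b.var(ddof=1), b.size)
    notes = mode
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        notes += "; degenerate: both groups constant and equal"
    return StatResult("t", float(res.statistic), (float(df),),
                      float(res.pvalue), method_notes=notes)


def ttest_from_summary(g1: SummaryGroup, g2: SummaryGroup,
                       mode: str = "pooled") -> StatResult:
    """The same statistic computed from printed mean/sd/n cells."""
    equal_var = mode == "pooled"
    res = stats.ttest_ind_from_stats(g1.mean, g1.sd, g1.n,
                                     g2.mean, g2.sd, g2.n,
                                     equal_var=equal_var)
    df = g1.n + g2.n - 2 if equal_var else _welch_df(g1.sd ** 2, g1.n,
                                                     g2.sd ** 2, g2.n)
    return StatResult("t", float(res.statistic), (float(df),),
                      float(res.pvalue), method_notes=f"{mode}, from summaries")


def _welch_df(v1: float, n1: int, v2: float, n2: int) -> float:
    a, b = v1 / n1, v2 / n2
    return (a + b) ** 2 / (a ** 2 / (n1 - 1) + b ** 2 / (n2 - 1))


def chi2_2x2(table) -> StatResult:
    """Pearson chi-square on a 2x2 count table, df=1, no Yates correction."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if np.any(table.sum(axis=0) <= 0) or np.any(table.sum(axis=1) <= 0):
        raise ValidationError("all marginals must be > 0")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return StatResult("chi2", float(chi2), (float(dof),), float(p),
                      method_notes="Pearson, no continuity correction")


def anova_oneway(groups) -> StatResult:
    groups = [np.asarray(g, dtype=float) for g in groups]
    _check_groups(groups)
    res = stats.f_oneway(*groups)
    k = len(groups)
    n = sum(g.size for g in groups)
    f_val = float(res.statistic)
    p_val = float(res.pvalue)
    if np.isnan(f_val):  # all groups constant and identical
        f_val, p_val = 0.0, 1.0
    return StatResult("F", f_val, (float(k - 1), float(n - k)), p_val)


def levene(groups) -> StatResult:
    """Levene's homogeneity-of-variance test with center='mean'."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    _check_groups(groups)
    res = stats.levene(*groups, center="mean")
    k = len(groups)
    n = sum(g.size for g in groups)
    f_val, p_val = float(res.statistic), float(res.pvalue)
    if np.isnan(f_val):
        f_val, p_val = 0.0, 1.0
    return StatResult("levene_F", f_val, (float(k - 1), float(n - k)), p_val)


def games_howell_pair(a, b) -> StatResult:
    """Games-Howell comparison of one pair.

    Welch-type t with Welch-Satterthwaite df; p = P(Q >= |t| sqrt(2)) under
    the studentized-range distribution with k groups (supplied by
    :func:`posthoc`; here k=2 ... the pairwise building block).
    """
    return _games_howell(np.asarray(a, float), np.asarray(b, float), k=2)


def _games_howell(a, b, k: int) -> StatResult:
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    n1, n2 = a.size, b.size
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        return StatResult("games_howell_t", 0.0, (float(n1 + n2 - 2),), 1.0,
                          method_notes="degenerate: zero variance")
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = _welch_df(v1, n1, v2, n2)
    p = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))
    return StatResult("games_howell_t", float(t), (float(df),),
                      min(max(p, 0.0), 1.0),
                      method_notes=f"studentized range, k={k}")


def posthoc(groups, method: str = "auto", alpha: float = 0.05,
            labels=None) -> list[tuple[str, str, StatResult]]:
    """Pairwise post hoc comparisons after a one-way ANOVA.

    ``method='auto'`` follows the study's rule: Levene's test (center=mean)
    decides — heterogeneous variances (p < alpha) use Games-Howell,
    homogeneous use Bonferroni-corrected pooled t-tests.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    _check_groups(groups)
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    if method == "auto":
        method = "games_howell" if levene(groups).p_two_tailed < alpha else "bonferroni"
    pairs = list(itertools.combinations(range(len(groups)), 2))
    out = []
    for i, j in pairs:
        if method == "games_howell":
            res = _games_howell(groups[i], groups[j], k=len(groups))
        elif method == "bonferroni":
            base = ttest_independent(groups[i], groups[j], mode="pooled")
            res = StatResult("t", base.statistic_value, base.df,
                             min(base.p_two_tailed * len(pairs), 1.0),
                             method_notes=f"Bonferroni x{len(pairs)}")
        else:
            raise ValidationError(f"unknown post hoc method '{method}'")
        out.append((labels[i], labels[j], res))
    return out


def _check_groups(groups) -> None:
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValidationError("every group needs n >= 2")


# ---------------------------------------------------------------------------
# Permutation oracles (seeded): brute-force references for the analytic p's.


def permutation_pearson_p(x, y, n_perm: int = 10_000, seed: int = 0) -> float:
    """Two-tailed permutation p for the Pearson correlation (label shuffle)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rng = np.random.default_rng(seed)
    r_obs = abs(np.corrcoef(x, y)[0, 1])
    idx = np.argsort(rng.random((n_perm, y.size)), axis=1)
    perms = y[idx]
    xc = (x - x.mean()) / x.std()
    pc = (perms - perms.mean(axis=1, keepdims=True)) / perms.std(axis=1, keepdims=True)
    r_perm = np.abs(pc @ xc) / x.size
    return float((np.sum(r_perm >= r_obs - 1e-12) + 1) / (n_perm + 1))


def permutation_ttest_p(a, b, n_perm: int = 10_000, seed: int = 0) -> float:
    """Two-tailed permutation p for the difference of means."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    obs = abs(a.mean() - b.mean())
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[: a.size].mean() - perm[a.size:].mean()) >= obs - 1e-12:
            count += 1
    return float((count + 1) / (n_perm + 1))


__all__ = [
    "StatResult", "SummaryGroup", "pearson_r_p", "p_from_r_n",
    "ttest_independent", "ttest_from_summary", "chi2_2x2",
    "anova_oneway", "levene", "games_howell_pair", "posthoc",
    "permutation_pearson_p", "permutation_ttest_p",
]
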