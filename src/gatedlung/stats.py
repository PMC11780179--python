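"""Group-comparison statistics for study metrics (alpha = 0.05).

Image-based lung metrics are compared with classical one-way ANOVA plus
Tukey's HSD (Tukey-Kramer for unequal n); heteroscedastic outcomes such
as body weight use Welch's and Brown-Forsythe's ANOVA with Dunnett's T3
post hoc test.  Statistics are computed from their defining formulas;
p-values come from scipy's F, t and studentized-range distributions,
except the studentized maximum modulus (Dunnett T3), which has no closed
form here and is evaluated by fixed-seed Monte Carlo.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05
SMM_DRAWS = 1_000_000
SMM_SEED = 180_449  # fixed seed of the studentized-maximum-modulus MC


@dataclass
class GroupData:
    """Metric values per group."""

    groups: dict[str, np.ndarray]
    metric: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, float).ravel() for k, v in self.groups.items()}
        for name, v in self.groups.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"group {name!r} contains non-finite values")


def _as_groups(data) -> dict[str, np.ndarray]:
    if isinstance(data, GroupData):
        return data.groups
    return {k: np.asarray(v, float).ravel() for k, v in dict(data).items()}


def _check_omnibus(groups: Mapping[str, np.ndarray]) -> None:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {name!r} has n={len(v)}; need n >= 2")


@dataclass
class ComparisonResult:
    """Omnibus statistic with optional pairwise post-hoc table."""

    method: str
    statistic: float
    df: tuple[float, float]
    p_value: float
    pairwise: pd.DataFrame | None = None
    alpha: float = ALPHA


def describe_groups(data) -> pd.DataFrame:
    """Descriptive statistics (n, mean, sd, sem, 95% CI, min, max) per group."""
    rows = []
    for name, v in _as_groups(data).items():
        n = len(v)
        sd = float(np.std(v, ddof=1)) if n > 1 else np.nan
        sem = sd / math.sqrt(n) if n > 1 else np.nan
        half = sps.t.ppf(0.975, n - 1) * sem if n > 1 else np.nan
        m = float(np.mean(v))
        rows.append(
            dict(group=name, n=n, mean=m, sd=sd, sem=sem,
                 ci95_lo=m - half, ci95_hi=m + half,
                 min=float(np.min(v)), max=float(np.max(v)))
        )
    return pd.DataFrame(rows)


def _sums_of_squares(groups: Mapping[str, np.ndarray]):
    ns = np.array([len(v) for v in groups.values()])
    means = np.array([v.mean() for v in groups.values()])
    grand = np.concatenate(list(groups.values())).mean()
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((v - v.mean()) ** 2).sum() for v in groups.values()))
    return ns, means, ssb, ssw


def one_way_anova(data) -> ComparisonResult:
    """Classical one-way ANOVA: F = MSB/MSW with (k-1, N-k) df."""
    groups = _as_groups(data)
    _check_omnibus(groups)
    ns, means, ssb, ssw = _sums_of_squares(groups)
    k = len(groups)
    N = int(ns.sum())
    df1, df2 = k - 1, N - k
    msb = ssb / df1
    msw = ssw / df2
    if msw == 0:
        if msb == 0:
            return ComparisonResult("one-way ANOVA", 0.0, (df1, df2), 1.0)
        import warnings

        warnings.warn("zero within-group variance with unequal means; p = 0", stacklevel=2)
        return ComparisonResult("one-way ANOVA", np.inf, (df1, df2), 0.0)
    F = msb / msw
    p = float(sps.f.sf(F, df1, df2))
    return ComparisonResult("one-way ANOVA", F, (df1, df2), p)


def tukey_hsd(data, alpha: float = ALPHA) -> pd.DataFrame:
    """Tukey's HSD pairwise table (Tukey-Kramer for unequal n).

    For each pair, ``q = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j))``
    with the adjusted p from the studentized-range distribution at
    (k, N-k).
    """
    groups = _as_groups(data)
    _check_omnibus(groups)
    ns, means, ssb, ssw = _sums_of_squares(groups)
    names = list(groups)
    k = len(groups)
    N = int(ns.sum())
    df2 = N - k
    msw = ssw / df2
    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(names), 2):
        diff = means[i] - means[j]
        if msw == 0:
            p_adj = 1.0 if diff == 0 else 0.0
            q = 0.0 if diff == 0 else np.inf
        else:
            se = math.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(q, k, df2))
        rows.append(
            dict(pair=f"{a} vs {b}", group_a=a, group_b=b, estimate=diff,
                 q=q, p_adj=min(p_adj, 1.0), significant=p_adj < alpha)
        )
    return pd.DataFrame(rows)


def _welch_weights(groups: Mapping[str, np.ndarray]):
    ns = np.array([len(v) for v in groups.values()], float)
    means = np.array([v.mean() for v in groups.values()])
    variances = np.array([v.var(ddof=1) for v in groups.values()])
    if np.any(variances == 0):
        raise ValueError("zero within-group variance: heteroscedastic weights undefined")
    w = ns / variances
    return ns, means, variances, w


def welch_anova(data) -> ComparisonResult:
    """Welch's heteroscedastic one-way ANOVA with Satterthwaite-type df."""
    groups = _as_groups(data)
    _check_omnibus(groups)
    ns, means, variances, w = _welch_weights(groups)
    k = len(groups)
    W = w.sum()
    mw = (w * means).sum() / W
    A = (w * (means - mw) ** 2).sum() / (k - 1)
    hterm = (((1.0 - w / W) ** 2) / (ns - 1.0)).sum()
    F = A / (1.0 + 2.0 * (k - 2) / (k**2 - 1.0) * hterm)
    df1 = k - 1.0
    df2 = (k**2 - 1.0) / (3.0 * hterm)
    p = float(sps.f.sf(F, df1, df2))
    return ComparisonResult("Welch ANOVA", float(F), (df1, df2), p)


def brown_forsythe(data) -> ComparisonResult:
    """Brown-Forsythe ANOVA for means: F* = SSB / sum((1-n_i/N) s_i^2)."""
    groups = _as_groups(data)
    _check_omnibus(groups)
    ns, means, variances, _ = _welch_weights(groups)
    _, _, ssb, _ = _sums_of_squares(groups)
    k = len(groups)
    N = ns.sum()
    denom_terms = (1.0 - ns / N) * variances
    denom = denom_terms.sum()
    F = ssb / denom
    c = denom_terms / denom
    df1 = k - 1.0
    df2 = 1.0 / ((c**2 / (ns - 1.0)).sum())
    p = float(sps.f.sf(F, df1, df2))
    return ComparisonResult("Brown-Forsythe ANOVA", float(F), (df1, df2), p)


def _smm_sf(q: float, n_comparisons: int, df: float, n_draws: int, seed: int) -> float:
    """P(studentized maximum modulus >= q) by Monte Carlo.

    SMM(C, df) = max of C independent |N(0,1)| divided by an independent
    chi(df)/sqrt(df).
    """
    rng = np.random.default_rng(seed)
    z = np.abs(rng.standard_normal((n_draws, n_comparisons))).max(axis=1)
    s = np.sqrt(rng.chisquare(df, n_draws) / df)
    return float(np.mean(z / s >= q))


def dunnett_t3(
    data,
    alpha: float = ALPHA,
    n_draws: int = SMM_DRAWS,
    seed: int = SMM_SEED,
) -> pd.DataFrame:
    """Dunnett's T3 all-pairs table for heteroscedastic groups.

    Pairwise Welch-type t statistics with Satterthwaite df, adjusted
    through the studentized maximum modulus distribution (Monte Carlo with
    ``n_draws`` fixed-seed draws).
    """
    groups = _as_groups(data)
    _check_omnibus(groups)
    ns, means, variances, _ = _welch_weights(groups)
    names = list(groups)
    k = len(names)
    C = k * (k - 1) // 2
    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(names), 2):
        se2_i = variances[i] / ns[i]
        se2_j = variances[j] / ns[j]
        t = (means[i] - means[j]) / math.sqrt(se2_i + se2_j)
        df = (se2_i + se2_j) ** 2 / (
            se2_i**2 / (ns[i] - 1.0) + se2_j**2 / (ns[j] - 1.0)
        )
        p_adj = _smm_sf(abs(t), C, df, n_draws, seed)
        rows.append(
            dict(pair=f"{a} vs {b}", group_a=a, group_b=b,
                 estimate=means[i] - means[j], t=t, df=df,
                 p_adj=p_adj, significant=p_adj < alpha)
        )
    return pd.DataFrame(rows)


def permutation_oracle(
    data,
    statistic: Callable[[Sequence[np.ndarray]], float] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Label-permutation p-value for an omnibus statistic (test oracle).

    By default the statistic is the classical F.  ``p = (1 + #{perm >=
    obs}) / (1 + n_perm)``, deterministic given ``seed``.
    """
    if n_perm < 1000:
        raise ValueError("use at least 1000 permutations")
    groups = _as_groups(data)
    _check_omnibus(groups)
    if statistic is None:
        def statistic(parts):
            res = one_way_anova({i: p for i, p in enumerate(parts)})
            return res.statistic

    pooled = np.concatenate(list(groups.values()))
    sizes = [len(v) for v in groups.values()]
    bounds = np.cumsum(sizes)[:-1]
    obs = statistic(list(groups.values()))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        parts = np.split(perm, bounds)
        if statistic(parts) >= obs:
            count += 1
    return (1.0 + count) / (1.0 + n_perm)


def compare_groups(
    study: pd.DataFrame,
    metric: str,
    group_col: str = "group",
    method: str = "anova_tukey",
    alpha: float = ALPHA,
) -> ComparisonResult:
    """Run an omnibus test plus its post hoc on a long-format table.

    ``method`` is ``anova_tukey`` (image metrics) or ``welch_t3``
    (heteroscedastic outcomes; the Brown-Forsythe omnibus is reported in
    the pairwise table's attrs).
    """
    groups = {
        name: sub[metric].to_numpy(float)
        for name, sub in study.groupby(group_col)
    }
    gd = GroupData(groups, metric=metric)
    if method == "anova_tukey":
        res = one_way_anova(gd)
        res.pairwise = tukey_hsd(gd, alpha)
    elif method == "welch_t3":
        res = welch_anova(gd)
        res.pairwise = dunnett_t3(gd, alpha)
        res.pairwise.attrs["brown_forsythe"] = brown_forsythe(gd)
    else:
        raise ValueError(f"unknown method {method!r}")
    res.alpha = alpha
    return res
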