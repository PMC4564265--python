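"""Greenhouse preference and performance statistics.

Preference trials offer an insect a pair of plants from the extremes of one
colour metric (high vs low B:G, DR:G, or brightness); pairs are formed by
ranking each extreme group and matching rank 1 with rank 1, and choices are
analysed with exact two-tailed binomial tests against p0 = 0.5.

Performance responses (relative growth rate, pupal mass, time to pupation,
leaf area eaten, aphid counts) are compared between colour groups with
one-way linear models (optionally on the natural-log scale), proportions
with quasibinomial GLMs, and glucosinolate levels with Mann-Whitney and
Wilcoxon matched-pairs tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .survey import ModelResult

__all__ = [
    "pair_by_rank",
    "exact_binomial_two_tailed",
    "compare_performance",
    "quasibinomial_proportion_test",
    "mann_whitney",
    "wilcoxon_matched",
    "percent_difference",
    "relative_growth_rate",
]


def pair_by_rank(values: Mapping[str, float], k: int = 30) -> list[tuple[str, str]]:
    """Select the k highest and k lowest plants and pair them by rank.

    Rank 1 of the high group (largest value overall) is paired with rank 1 of
    the low group (smallest value overall), rank 2 with rank 2, and so on.
    Ties are broken by stable plant-id order.  Requires at least 2k plants.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    items = sorted(values.items(), key=lambda kv: kv[0])  # stable id order
    if len(items) < 2 * k:
        raise ValueError(f"need at least {2 * k} plants for k={k} pairs, got {len(items)}")
    by_value = sorted(items, key=lambda kv: kv[1])
    low = [pid for pid, _ in by_value[:k]]              # ascending: most extreme low first
    high = [pid for pid, _ in reversed(by_value[-k:])]  # descending: most extreme high first
    return list(zip(high, low))


def exact_binomial_two_tailed(successes: int, trials: int, p0: float = 0.5) -> float:
    """Exact two-tailed binomial p-value by the doubling rule.

    p = min(1, 2 * min(P(X <= k), P(X >= k))) under Binomial(n, p0).  For
    p0 = 0.5 this coincides with the point-probability ('minlike') rule.
    """
    if not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials")
    lower = stats.binom.cdf(successes, trials, p0)
    upper = stats.binom.sf(successes - 1, trials, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))


def relative_growth_rate(mass_start_mg: float, mass_end_mg: float,
                         days_start: float, days_end: float) -> float:
    """Relative growth rate (ln m2 - ln m1) / (t2 - t1), in mg/mg/day."""
    if mass_start_mg <= 0 or mass_end_mg <= 0:
        raise ValueError("masses must be positive for the log growth rate")
    if days_end <= days_start:
        raise ValueError("end day must exceed start day")
    return float((np.log(mass_end_mg) - np.log(mass_start_mg)) / (days_end - days_start))


def compare_performance(
    records: pd.DataFrame,
    response: str,
    group: str = "group",
    transform: str = "none",
    plant_id: str | None = "plant_id",
) -> ModelResult:
    """One-way linear model comparing a performance response between groups.

    When several larvae share a plant, plant-level means are taken first so
    the plant is the experimental unit.  ``transform="log"`` applies the
    natural log (zero or negative responses are an error; no offset is
    added).  Returns the F statistic for dropping the group term, with group
    means +/- SEM in ``fit_info``.
    """
    df = records[[c for c in {response, group, plant_id} if c]].dropna().copy()
    if plant_id and plant_id in df.columns:
        df = df.groupby([group, plant_id], as_index=False)[response].mean()
    y = df[response].astype(float).to_numpy()
    if transform == "log":
        if np.any(y <= 0):
            raise ValueError("log transform requires strictly positive responses")
        y = np.log(y)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    codes, levels = pd.factorize(df[group], sort=True)
    if len(levels) < 2 or np.any(np.bincount(codes) < 2):
        raise ValueError("need >= 2 groups with >= 2 plants each")
    X = np.column_stack([np.ones(len(y))] + [(codes == g).astype(float) for g in range(1, len(levels))])
    fit = sm.OLS(y, X).fit()
    if fit.ssr == 0:
        # identical values in both groups: F = 0 / 0-variance; treat as no effect
        return ModelResult(
            terms={str(levels[g]): 0.0 for g in range(1, len(levels))},
            test="F", statistic=0.0, df=(float(len(levels) - 1), float(len(y) - len(levels))),
            p_value=1.0, fit_info={"note": "zero residual variance"},
        )
    null = sm.OLS(y, np.ones((len(y), 1))).fit()
    df1 = float(len(levels) - 1)
    df2 = float(len(y) - len(levels))
    F = ((null.ssr - fit.ssr) / df1) / (fit.ssr / df2)
    p = float(stats.f.sf(F, df1, df2))
    means = {}
    for g, lv in enumerate(levels):
        vals = y[codes == g]
        means[str(lv)] = {
            "mean": float(vals.mean()),
            "sem": float(vals.std(ddof=1) / np.sqrt(len(vals))),
            "n": int(len(vals)),
        }
    return ModelResult(
        terms={f"{group}[{levels[g]}]": float(fit.params[g]) for g in range(1, len(levels))},
        test="F", statistic=float(F), df=(df1, df2), p_value=p,
        fit_info={"group_stats": means, "transform": transform},
    )


def quasibinomial_proportion_test(
    numerators: Sequence[int],
    denominators: Sequence[int],
    group: Sequence,
) -> ModelResult:
    """Quasibinomial GLM testing a group effect on a proportion.

    A binomial GLM is fitted to (successes, failures); the dispersion is
    estimated as Pearson chi-square over residual df and the group term is
    tested by a dispersion-scaled F on the change in deviance.
    """
    num = np.asarray(numerators, dtype=float)
    den = np.asarray(denominators, dtype=float)
    if np.any(den <= 0):
        raise ValueError("denominators must be positive")
    if np.any(num < 0) or np.any(num > den):
        raise ValueError("need 0 <= numerators <= denominators")
    codes, levels = pd.factorize(pd.Series(group), sort=True)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    endog = np.column_stack([num, den - num])
    X = np.column_stack([np.ones(len(num))] + [(codes == g).astype(float) for g in range(1, len(levels))])
    full = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
    null = sm.GLM(endog, np.ones((len(num), 1)), family=sm.families.Binomial()).fit()
    df_resid = float(full.df_resid)
    phi = float(full.pearson_chi2) / df_resid
    df1 = float(len(levels) - 1)
    dchange = float(null.deviance - full.deviance)
    if dchange <= 1e-12:
        F, p = 0.0, 1.0
    elif phi <= 0:          # no residual variability at all
        F, p = np.inf, 0.0
    else:
        F = (dchange / df1) / phi
        p = float(stats.f.sf(F, df1, df_resid))
    return ModelResult(
        terms={f"group[{levels[g]}]": float(full.params[g]) for g in range(1, len(levels))},
        test="F", statistic=float(F), df=(df1, df_resid), p_value=p,
        fit_info={"dispersion": phi, "deviance": float(full.deviance)},
    )


_EXACT_LIMIT = 12  # combined sample size below which exact enumeration is used


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> ModelResult:
    """Mann-Whitney test; W is the U statistic of the first sample.

    Exact enumeration when n + m <= 12 and there are no cross-sample ties;
    otherwise the normal approximation with tie correction and continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("each sample needs at least one observation")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size + y.size <= _EXACT_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return ModelResult(
        terms={}, test="W", statistic=float(res.statistic),
        df=(float(x.size), float(y.size)), p_value=float(res.pvalue),
        fit_info={"method": method,
                  "convention": "U statistic of the first sample (rank-sum minus n1(n1+1)/2)"},
    )


def wilcoxon_matched(before: Sequence[float], after: Sequence[float]) -> ModelResult:
    """Wilcoxon matched-pairs signed-rank test; W is the positive-rank sum.

    Zero differences are dropped (Wilcoxon's rule); all-zero differences are
    an error.  Exact sign-flip enumeration for <= 12 non-zero differences
    without tied magnitudes, else the normal approximation with tie and
    continuity corrections.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.size != a.size:
        raise ValueError("matched samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero; the test carries no information")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    tied = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= _EXACT_LIMIT and not tied) else "approx"
    res = stats.wilcoxon(a, b, alternative="two-sided", zero_method="wilcox",
                         correction=(method == "approx"), method=method)
    return ModelResult(
        terms={}, test="W", statistic=w_plus, df=(float(d.size),),
        p_value=float(res.pvalue),
        fit_info={"method": method, "convention": "sum of ranks of positive differences"},
    )


def percent_difference(a: float, b: float) -> float:
    """Percent difference of ``a`` relative to reference mean ``b``: 100 (a - b) / b."""
    if b <= 0:
        raise ValueError("reference mean must be positive")
    return float(100.0 * (a - b) / b)
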