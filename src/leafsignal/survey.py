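"""Field-survey statistics: correlation screens, FDR control, presence GLMMs.

Plant records are a pandas DataFrame with one row per surveyed plant:
colour metrics (``bg_ratio``, ``prg_ratio``, ``drg_ratio``, ``brightness``),
eight glucosinolate concentrations plus their totals, covariates (``size_mm``,
``density``, ``flowering``, ``cn_ratio``), herbivore presence flags
(``presence_pieris``, ``presence_brassicae``) and ``population`` nested within
``county``.

The analysis stages mirror the field workflow: Spearman correlation screens
between colour channels and chemistry/covariates with Benjamini-Hochberg FDR
control; binomial GLMMs for herbivore presence with population-in-county
random intercepts, single colour predictors tested by change in deviance;
VIF collinearity screening; and backward deletion to a minimum adequate
model.  Colour predictors are z-scored before GLMM fitting for conditioning
(estimates are reported on both scales).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .glmm import MixedLogitResult, fit_binomial_mixed

__all__ = [
    "GS_NAMES",
    "GS_ALIPHATIC",
    "GS_INDOLE",
    "COLOUR_CHANNELS",
    "ModelResult",
    "spearman_matrix",
    "bh_adjust",
    "fit_presence_glmm",
    "lrt_drop_term",
    "marginal_r2",
    "vif",
    "backward_select",
    "forward_select",
    "p_from_chi2",
    "SelectionResult",
    "APHID_COUNTIES",
]

GS_ALIPHATIC = ("glucoiberin", "gluconapin", "glucoraphanin", "progoitrin", "sinigrin")
GS_INDOLE = ("glucobrassicin", "neoglucobrassicin", "4-methoxyglucobrassicin")
GS_NAMES = GS_ALIPHATIC + GS_INDOLE
COLOUR_CHANNELS = ("bg_ratio", "prg_ratio", "drg_ratio", "brightness")

#: counties where the cabbage aphid occurs; Kent is excluded from aphid analyses.
APHID_COUNTIES = ("Cornwall", "Devon", "Dorset")


@dataclass
class ModelResult:
    """Outcome of one statistical test or model stage."""

    terms: dict[str, float]
    test: str                      # statistic name: 'chi2', 'F', 'rho', 'W', ...
    statistic: float
    df: tuple[float, ...]
    p_value: float
    adjusted_significant: bool | None = None
    fit_info: dict = field(default_factory=dict)


def spearman_matrix(
    records: pd.DataFrame,
    vars_x: Sequence[str],
    vars_y: Sequence[str],
) -> pd.DataFrame:
    """Spearman rank correlations for every (x, y) pair, pairwise-complete.

    Returns a long DataFrame with columns ``x, y, rho, p, n``.  Ties receive
    average ranks; p-values use the large-sample t approximation.  Pairs with
    fewer than 3 complete cases or a constant variable are flagged with NaN.
    """
    rows = []
    for xv in vars_x:
        for yv in vars_y:
            sub = records[[xv, yv]].dropna()
            n = len(sub)
            if n < 3 or sub[xv].nunique() < 2 or sub[yv].nunique() < 2:
                rows.append({"x": xv, "y": yv, "rho": np.nan, "p": np.nan, "n": n})
                continue
            rho, p = stats.spearmanr(sub[xv], sub[yv])
            rows.append({"x": xv, "y": yv, "rho": float(rho), "p": float(p), "n": n})
    return pd.DataFrame(rows)


def bh_adjust(p_values: Sequence[float], fdr_q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(reject, p_adjusted)``: ``reject`` marks the k smallest p-values
    where k = max{i : p_(i) <= (i/m) q}; adjusted p-values are the monotone
    step-up envelope min_j>=i (m p_(j) / j), capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=fdr_q, method="fdr_bh")
    return reject, p_adj


def _prepare_presence(
    records: pd.DataFrame,
    response: str,
    fixed: Sequence[str],
    county_filter: Sequence[str] | None,
    standardize: bool,
):
    col = {"pieris": "presence_pieris", "brassicae": "presence_brassicae"}.get(response, response)
    df = records
    if county_filter is not None:
        df = df[df["county"].isin(county_filter)]
    df = df.dropna(subset=[col, *fixed]).copy()
    y = df[col].astype(float).to_numpy()
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError(f"response {col!r} must be binary 0/1")
    cols = [np.ones(len(df))]
    names = ["intercept"]
    scales = {}
    for v in fixed:
        x = df[v].astype(float).to_numpy()
        if standardize:
            mu, sd = float(np.mean(x)), float(np.std(x))
            if sd == 0:
                raise ValueError(f"predictor {v!r} is constant")
            x = (x - mu) / sd
            scales[v] = (mu, sd)
        cols.append(x)
        names.append(v)
    X = np.column_stack(cols)
    county_codes, _ = pd.factorize(df["county"], sort=True)
    pop_codes, _ = pd.factorize(df["population"], sort=True)
    return y, X, tuple(names), county_codes, pop_codes, df, scales


def fit_presence_glmm(
    records: pd.DataFrame,
    response: str,
    fixed: Sequence[str],
    county_filter: Sequence[str] | None = None,
    standardize: bool = True,
) -> MixedLogitResult:
    """Binomial GLMM for herbivore presence with population-in-county intercepts.

    ``response`` is ``"pieris"``, ``"brassicae"`` or an explicit column name.
    Rows with a missing response or predictor are dropped (listwise).  Colour
    predictors are z-scored by default; raw-scale coefficients are recorded in
    the result's ``flags``-free metadata via the standardisation scales.
    Aphid analyses should pass ``county_filter=APHID_COUNTIES``.
    """
    y, X, names, ci, pi, df, scales = _prepare_presence(
        records, response, fixed, county_filter, standardize
    )
    res = fit_binomial_mixed(y, X, ci, pi, term_names=names)
    if scales and res.ok:
        res.raw_scale_coefs = {v: res.coef(v) / scales[v][1] for v in scales}  # type: ignore[attr-defined]
    return res


def lrt_drop_term(full: MixedLogitResult, reduced: MixedLogitResult, df: int = 1) -> ModelResult:
    """Likelihood-ratio test for a term dropped from ``full`` to ``reduced``.

    chi-square = deviance(reduced) - deviance(full), floored at 0, with the
    stated degrees of freedom.  Both fits must be on identical data with the
    reduced fixed structure nested in the full one.
    """
    if full.n != reduced.n or full.response_checksum != reduced.response_checksum:
        raise ValueError("full and reduced models were fitted on different data")
    if not set(reduced.terms).issubset(full.terms):
        raise ValueError("reduced model terms are not a subset of the full model's")
    chi2 = max(0.0, reduced.deviance - full.deviance)
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    dropped = sorted(set(full.terms) - set(reduced.terms))
    return ModelResult(
        terms={t: full.coef(t) for t in dropped},
        test="chi2",
        statistic=chi2,
        df=(float(df),),
        p_value=p,
        fit_info={"deviance_full": full.deviance, "deviance_reduced": reduced.deviance},
    )


def p_from_chi2(chi2: float, df: int = 1) -> float:
    """Upper-tail p-value for a chi-square statistic (deviance-change test)."""
    return float(stats.chi2.sf(chi2, df))


def marginal_r2(model: MixedLogitResult) -> float:
    """Nakagawa-Schielzeth marginal R-squared for the logistic mixed model.

    var_fixed / (var_fixed + sigma_county^2 + sigma_pop^2 + pi^2/3), where
    var_fixed is the variance of the fixed-effect linear predictor and
    pi^2/3 the logit-link distribution variance.
    """
    denom = model.var_fixed + model.sigma_county**2 + model.sigma_pop**2 + np.pi**2 / 3.0
    return float(model.var_fixed / denom)


def vif(records: pd.DataFrame, predictors: Sequence[str]) -> pd.Series:
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j).

    Each predictor is regressed (OLS with intercept) on all the others over
    the listwise-complete rows.  Exact collinearity yields ``inf``.
    Conventional flags: VIF > 3 moderate, VIF > 10 severe collinearity.
    """
    if len(predictors) < 2:
        raise ValueError("VIF needs at least two predictors")
    df = records[list(predictors)].dropna()
    if len(df) <= len(predictors):
        raise ValueError("need more complete rows than predictors")
    out = {}
    Xall = df.to_numpy(dtype=float)
    for j, name in enumerate(predictors):
        yj = Xall[:, j]
        Xo = np.column_stack([np.ones(len(df)), np.delete(Xall, j, axis=1)])
        coefs, _, _, _ = np.linalg.lstsq(Xo, yj, rcond=None)
        resid = yj - Xo @ coefs
        sst = float(np.sum((yj - yj.mean()) ** 2))
        if sst == 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - float(np.sum(resid**2)) / sst
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


@dataclass
class SelectionResult:
    """Backward/forward selection outcome: final model plus the deletion trace."""

    model: MixedLogitResult
    retained: tuple[str, ...]
    trace: list[dict]
    final_tests: dict[str, ModelResult]


def _fit_subset(records, response, terms, county_filter, standardize):
    return fit_presence_glmm(
        records, response, list(terms), county_filter=county_filter, standardize=standardize
    )


def backward_select(
    records: pd.DataFrame,
    response: str,
    global_fixed: Sequence[str],
    alpha: float = 0.05,
    county_filter: Sequence[str] | None = None,
    standardize: bool = True,
) -> SelectionResult:
    """Backward deletion to a minimum adequate model.

    Starting from the global fixed structure, the least significant term
    (largest deviance-change p on removal) is dropped while its p exceeds
    ``alpha``; ties are broken by dropping the term declared later.  Every
    term retained increases deviance significantly when removed.  Rows are
    restricted once to those complete for the global model so every nested
    fit uses identical data.
    """
    needed = ["county", "population",
              {"pieris": "presence_pieris", "brassicae": "presence_brassicae"}.get(response, response),
              *global_fixed]
    base = records
    if county_filter is not None:
        base = base[base["county"].isin(county_filter)]
    base = base.dropna(subset=[c for c in needed if c in base.columns])

    terms = list(global_fixed)
    trace: list[dict] = []
    current = _fit_subset(base, response, terms, None, standardize)
    if not current.ok:
        raise RuntimeError(f"global model failed: flags={current.flags}")
    while terms:
        tests = {}
        for t in terms:
            reduced = _fit_subset(base, response, [x for x in terms if x != t], None, standardize)
            tests[t] = lrt_drop_term(current, reduced, df=1)
        # largest p first; tie-break = later declared order
        order = {t: i for i, t in enumerate(global_fixed)}
        worst = max(terms, key=lambda t: (tests[t].p_value, order[t]))
        if tests[worst].p_value <= alpha:
            final_tests = tests
            break
        trace.append({"dropped": worst, "p": tests[worst].p_value, "chi2": tests[worst].statistic})
        terms.remove(worst)
        current = _fit_subset(base, response, terms, None, standardize)
    else:
        final_tests = {}
    return SelectionResult(
        model=current, retained=tuple(terms), trace=trace, final_tests=final_tests
    )


def forward_select(
    records: pd.DataFrame,
    response: str,
    candidates: Sequence[str],
    alpha: float = 0.05,
    county_filter: Sequence[str] | None = None,
    standardize: bool = True,
) -> SelectionResult:
    """Forward selection counterpart used to confirm the backward result."""
    needed = ["county", "population",
              {"pieris": "presence_pieris", "brassicae": "presence_brassicae"}.get(response, response),
              *candidates]
    base = records
    if county_filter is not None:
        base = base[base["county"].isin(county_filter)]
    base = base.dropna(subset=[c for c in needed if c in base.columns])

    terms: list[str] = []
    remaining = list(candidates)
    trace: list[dict] = []
    current = _fit_subset(base, response, terms, None, standardize)
    while remaining:
        tests = {}
        for t in remaining:
            bigger = _fit_subset(base, response, terms + [t], None, standardize)
            tests[t] = lrt_drop_term(bigger, current, df=1)
        order = {t: i for i, t in enumerate(candidates)}
        best = min(remaining, key=lambda t: (tests[t].p_value, order[t]))
        if tests[best].p_value > alpha:
            break
        trace.append({"added": best, "p": tests[best].p_value, "chi2": tests[best].statistic})
        terms.append(best)
        remaining.remove(best)
        current = _fit_subset(base, response, terms, None, standardize)
    return SelectionResult(model=current, retained=tuple(terms), trace=trace, final_tests={})
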