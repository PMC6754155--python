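"""Regression screening of tidal-volume determinants.

The outcome throughout is the lowest standardized tidal volume (V^T, mL/kg
PBW).  Continuous factors are min-max rescaled to [0, 1] so coefficients are
comparable; binary factors enter as 0/1; the admitting ICU enters as
indicator contrasts against the largest unit.  Significance uses
alpha = 0.01 with Bonferroni correction (33 regression comparisons ->
p < 0.0003; 2 covariate fits -> p < 0.005), both sourced from
:class:`~ardsrec.types.AnalysisConfig`.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .errors import (CollinearityError, DegenerateInputError, EmptyResultError,
                     InvalidFactorError, InvalidInputError)
from .types import AnalysisConfig, Cohort, PatientRecord, RegressionResult

#: factors restricted to a single cohort
_COHORT_ONLY = {"bilateral_infiltrates": Cohort.CONTROL, "admitting_icu": Cohort.ARDS}
#: factors that are already on a [0, 1] scale and are never min-max rescaled
_BINARY_FACTORS = {"documented", "bilateral_infiltrates"}
_CATEGORICAL_FACTORS = {"admitting_icu"}

SCREEN_FACTORS_ARDS = ["pbw_kg", "pf_lowest", "pf_first", "documented",
                       "pplat_highest", "admit_weight_kg", "admitting_icu"]
SCREEN_FACTORS_CONTROL = ["pbw_kg", "pf_lowest", "pf_first", "documented",
                          "pplat_highest", "admit_weight_kg",
                          "bilateral_infiltrates"]


def rescale_unit(values: Sequence[float]) -> np.ndarray:
    """Min-max rescale to [0, 1]; missing entries pass through as NaN."""
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 2:
        raise DegenerateInputError("need at least 2 non-missing values to rescale")
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        raise DegenerateInputError("constant vector cannot be rescaled")
    return (x - lo) / (hi - lo)


def _check_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    offending = []
    cols = list(design.columns)
    for j in range(1, X.shape[1]):
        sub = X[:, :j]
        beta, *_ = np.linalg.lstsq(sub, X[:, j], rcond=None)
        if np.allclose(sub @ beta, X[:, j], atol=1e-8):
            offending.append(cols[j])
    raise CollinearityError(offending or cols[1:])


def fit_ols(y: Sequence[float], X: pd.DataFrame,
            interactions: Optional[Sequence[tuple[str, str]]] = None,
            outcome: str = "vt_std",
            config: Optional[AnalysisConfig] = None) -> RegressionResult:
    """OLS of ``y`` on the columns of ``X`` plus optional pairwise products.

    Complete cases only; 99% CIs from the t distribution with n-p-1 df;
    AIC/BIC under the Gaussian likelihood.
    """
    cfg = config or AnalysisConfig()
    X = pd.DataFrame(X).copy()
    for a, b in interactions or []:
        X[f"{a}:{b}"] = X[a] * X[b]
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y) & np.isfinite(X.to_numpy(dtype=float)).all(axis=1)
    y, X = y[mask], X.loc[mask]
    p = X.shape[1]
    if len(y) <= p + 1:
        raise InvalidInputError(
            f"need n > p + 1 complete cases, got n={len(y)}, p={p}")
    design = sm.add_constant(X, has_constant="add")
    _check_rank(design)
    if np.ptp(y) == 0.0:
        # constant outcome: nothing to explain; coefficients are exactly 0
        # and the factors carry no evidence (p = 1)
        k = X.shape[1]
        return RegressionResult(
            outcome=outcome, factors=list(X.columns),
            betas=np.zeros(k), ci99=np.zeros((k, 2)), p_values=np.ones(k),
            n=int(len(y)), aic=-np.inf, bic=-np.inf, intercept=float(y[0]))
    res = sm.OLS(y, design).fit()
    ci = np.asarray(res.conf_int(alpha=cfg.alpha))
    betas = np.asarray(res.params)
    pvals = np.asarray(res.pvalues)
    # near-degenerate designs can make individual t ratios 0/0
    degenerate = ~np.isfinite(pvals) & np.isclose(betas, 0.0)
    pvals[degenerate] = 1.0
    ci[degenerate] = 0.0
    return RegressionResult(
        outcome=outcome, factors=list(X.columns),
        betas=betas[1:], ci99=ci[1:], p_values=pvals[1:],
        n=int(len(y)), aic=float(res.aic), bic=float(res.bic),
        intercept=float(betas[0]))


def fit_logistic(outcome: Sequence[float], x: Sequence[float],
                 factor_name: str = "x", outcome_name: str = "documented",
                 config: Optional[AnalysisConfig] = None) -> RegressionResult:
    """ML logistic fit of a binary outcome on one factor (Newton/IRLS).

    Perfect separation is flagged in ``status`` rather than raising.
    """
    cfg = config or AnalysisConfig()
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(x, dtype=float)
    mask = np.isfinite(y) & np.isfinite(x)
    y, x = y[mask], x[mask]
    if len(y) < 10:
        raise InvalidInputError(f"need at least 10 complete cases, got {len(y)}")
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateInputError("both outcome classes must be present")
    design = sm.add_constant(pd.DataFrame({factor_name: x}), has_constant="add")
    separated = False
    messages: list[str] = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, design).fit(method="newton", tol=1e-8,
                                          maxiter=100, disp=0)
        if np.abs(res.params[1:]).max() > 20 or not np.isfinite(res.bse).all():
            separated = True
    except (PerfectSeparationError, PerfectSeparationWarning,
            np.linalg.LinAlgError) as exc:
        separated = True
        messages.append(str(exc))
    if separated:
        messages.append("perfect separation: coefficients diverge")
        return RegressionResult(
            outcome=outcome_name, factors=[factor_name],
            betas=[np.nan], ci99=[(np.nan, np.nan)], p_values=[np.nan],
            n=int(len(y)), aic=np.nan, bic=np.nan,
            status="separation", messages=messages)
    ci = np.asarray(res.conf_int(alpha=cfg.alpha))
    return RegressionResult(
        outcome=outcome_name, factors=[factor_name],
        betas=np.asarray(res.params)[1:], ci99=ci[1:],
        p_values=np.asarray(res.pvalues)[1:],
        n=int(len(y)), aic=float(res.aic), bic=float(res.bic),
        intercept=float(np.asarray(res.params)[0]), messages=messages)


# --------------------------------------------------------------------------
# factor-column construction from records


def _factor_columns(records: Sequence[PatientRecord],
                    factor: str) -> pd.DataFrame:
    """Build the design column(s) for one factor, NaN for missing."""
    if factor in _CATEGORICAL_FACTORS:
        labels = pd.Series([r.admitting_icu for r in records], dtype=object)
        if labels.isna().all():
            raise DegenerateInputError(f"{factor}: all values missing")
        reference = labels.value_counts().idxmax()  # largest ICU as baseline
        levels = [l for l in sorted(labels.dropna().unique()) if l != reference]
        if not levels:
            raise DegenerateInputError(f"{factor}: single level only")
        return pd.DataFrame(
            {f"{factor}[{l}]": (labels == l).astype(float) for l in levels})
    raw = []
    for r in records:
        v = getattr(r, factor)
        raw.append(np.nan if v is None else float(v))
    col = np.asarray(raw, dtype=float)
    if not np.isfinite(col).any():
        raise DegenerateInputError(f"{factor}: all values missing")
    if factor not in _BINARY_FACTORS:
        col = rescale_unit(col)
    return pd.DataFrame({factor: col})


def _check_applicable(records: Sequence[PatientRecord], factor: str) -> None:
    required = _COHORT_ONLY.get(factor)
    if required is not None and any(r.cohort is not required for r in records):
        raise InvalidFactorError(
            f"factor {factor!r} applies only to the {required.value} cohort")


def univariable_screen(records: Sequence[PatientRecord],
                       factors: Sequence[str],
                       config: Optional[AnalysisConfig] = None
                       ) -> list[RegressionResult]:
    """One OLS of V^T per factor, flagged at the Bonferroni threshold.

    For multi-column factors (admitting ICU contrasts) the factor is flagged
    significant if any contrast clears the threshold.
    """
    cfg = config or AnalysisConfig()
    y = np.asarray([r.vt_std for r in records], dtype=float)
    out = []
    for factor in factors:
        _check_applicable(records, factor)
        X = _factor_columns(records, factor)
        result = fit_ols(y, X, outcome="vt_std", config=cfg)
        result.significant = bool(np.nanmin(result.p_values)
                                  < cfg.regression_threshold)
        out.append(result)
    return out


@dataclass
class ModelSelection:
    """Outcome of the all-subsets multivariable search."""

    status: str                      # "ok" | "skipped"
    best: Optional[RegressionResult] = None
    n_candidates: int = 0
    log: list[str] = field(default_factory=list)


def count_candidate_models(k: int) -> int:
    """Non-empty factor subsets, each with any subset of its pairwise
    interaction terms: sum over s of C(k, s) * 2^C(s, 2)."""
    from math import comb

    return sum(comb(k, s) * 2 ** comb(s, 2) for s in range(1, k + 1))


def multivariable_select(records: Sequence[PatientRecord],
                         factors: Sequence[str],
                         config: Optional[AnalysisConfig] = None
                         ) -> ModelSelection:
    """All-subsets OLS with optional pairwise interactions, ranked by AIC.

    Requires at least two candidate factors; with fewer the search is
    skipped (a single-factor multivariable model is just the univariable
    fit).  Ties break to fewer parameters, then lexicographic factor order.
    """
    cfg = config or AnalysisConfig()
    factors = sorted(factors)
    if len(factors) < 2:
        return ModelSelection(
            status="skipped",
            log=[f"only {len(factors)} significant factor(s); "
                 "no multivariable analysis performed"])
    y = np.asarray([r.vt_std for r in records], dtype=float)
    columns = {f: _factor_columns(records, f) for f in factors}
    candidates = []
    log = []
    for size in range(1, len(factors) + 1):
        for subset in itertools.combinations(factors, size):
            X_base = pd.concat([columns[f] for f in subset], axis=1)
            pairs = list(itertools.combinations(
                [c for f in subset for c in columns[f].columns], 2))
            for r in range(len(pairs) + 1):
                for inter in itertools.combinations(pairs, r):
                    try:
                        fit = fit_ols(y, X_base, interactions=list(inter),
                                      config=cfg)
                    except (CollinearityError, InvalidInputError) as exc:
                        log.append(f"{subset} + {inter}: skipped ({exc})")
                        continue
                    key = (fit.aic, len(fit.factors), tuple(fit.factors))
                    candidates.append((key, subset, inter, fit))
                    log.append(f"{'+'.join(fit.factors)}: "
                               f"AIC={fit.aic:.2f} BIC={fit.bic:.2f}")
    if not candidates:
        raise DegenerateInputError("no candidate model could be fitted")
    candidates.sort(key=lambda c: c[0])
    best = candidates[0][3]
    return ModelSelection(status="ok", best=best,
                          n_candidates=len(candidates), log=log)


def sensitivity_filter(records: Sequence[PatientRecord],
                       criterion: str) -> list[PatientRecord]:
    """Robustness cohorts: study duration strictly > 12 h, or PBW strictly
    inside the empirical 2.5-97.5 percentile interval."""
    if not records:
        raise InvalidInputError("record list must be non-empty")
    if criterion == "duration_gt_12h":
        kept = [r for r in records if r.study_duration_h > 12.0]
    elif criterion == "pbw_central_95":
        pbw = np.asarray([r.pbw_kg for r in records], dtype=float)
        lo, hi = np.percentile(pbw, [2.5, 97.5], method="linear")
        kept = [r for r in records if lo < r.pbw_kg < hi]
    else:
        raise InvalidInputError(f"unknown sensitivity criterion {criterion!r}")
    if not kept:
        raise EmptyResultError(f"criterion {criterion!r} removed every record")
    return kept


def covariate_analysis(records: Sequence[PatientRecord],
                       config: Optional[AnalysisConfig] = None
                       ) -> list[RegressionResult]:
    """Logistic fits of documentation on lowest P/F and on PBW, flagged at
    the covariate Bonferroni threshold (0.005)."""
    cfg = config or AnalysisConfig()
    doc = np.asarray([float(r.documented) for r in records])
    out = []
    for factor in ("pf_lowest", "pbw_kg"):
        x = rescale_unit([getattr(r, factor) for r in records])
        res = fit_logistic(doc, x, factor_name=factor, config=cfg)
        if res.status == "ok":
            res.significant = bool(res.p_values[0] < cfg.covariate_threshold)
        out.append(res)
    return out
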