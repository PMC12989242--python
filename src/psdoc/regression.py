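"""Logistic models of PS documentation with restricted-cubic-spline age.

Fits the two model variants for the binary ``has_ps`` outcome — without
and with metastatic status at diagnosis — on covariates sex, age (as a
restricted cubic spline with k knots, default 3), cancer group, hospital,
and the number of each report type, and reports odds ratios with Wald 95%
confidence intervals.

The restricted (natural) cubic spline basis follows the usual
truncated-power construction: with knots t_1 < ... < t_k the basis is the
linear term plus k-2 nonlinear columns

    z_j(x) = [ (x-t_j)^3_+ - (x-t_{k-1})^3_+ (t_k-t_j)/(t_k-t_{k-1})
               + (x-t_k)^3_+ (t_{k-1}-t_j)/(t_k-t_{k-1}) ] / (t_k-t_1)^2

which makes the fitted function linear beyond the boundary knots.  Knots
default to the 0.10 / 0.50 / 0.90 quantiles of the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "FitResult",
    "default_knots",
    "rcs_basis",
    "fit_logistic_design",
    "fit_logistic",
    "compare_models",
    "coefficient_table",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class ModelSpec:
    """Covariate specification for the PS-documentation logistic model."""

    include_metastatic: bool = False
    n_knots: int = 3
    knots: Sequence[float] | None = None  # explicit knots override quantiles
    reference_group: str = "Breast"
    reference_hospital: str | None = None  # None: largest hospital in data
    reference_sex: str = "F"

    def __post_init__(self) -> None:
        if self.n_knots < 3:
            raise ValueError("a restricted cubic spline needs k >= 3 knots")


@dataclass
class FitResult:
    """Coefficients, odds ratios and Wald 95% CIs from one logistic fit."""

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    odds_ratios: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    converged: bool
    n_obs: int
    log_likelihood: float
    separation_flags: list[str] = field(default_factory=list)

    def predicted(self, X: np.ndarray) -> np.ndarray:
        beta = np.array(list(self.coefficients.values()))
        return 1.0 / (1.0 + np.exp(-(X @ beta)))


def default_knots(x: np.ndarray, k: int = 3) -> np.ndarray:
    """Knots at evenly spaced outer quantiles (0.10 .. 0.90 for k = 3)."""
    qs = np.linspace(0.10, 0.90, k)
    return np.quantile(np.asarray(x, dtype=float), qs)


def rcs_basis(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    """Design columns of the restricted cubic spline (k-1 columns).

    First column is x itself; the k-2 remaining columns are the nonlinear
    terms, scaled by (t_k - t_1)^2 so coefficients stay on a comparable
    scale.  Raises when the data has fewer distinct values than knots.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = len(t)
    if k < 3:
        raise ValueError("need at least 3 knots")
    if np.any(np.diff(t) <= 0):
        raise ValueError("knots must be strictly increasing")
    if len(np.unique(x)) < k:
        raise ValueError(
            f"degenerate basis: {len(np.unique(x))} distinct values for {k} knots")

    def ppart3(v):
        return np.clip(v, 0.0, None) ** 3

    scale = (t[-1] - t[0]) ** 2
    cols = [x]
    for j in range(k - 2):
        z = (
            ppart3(x - t[j])
            - ppart3(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + ppart3(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        ) / scale
        cols.append(z)
    return np.column_stack(cols)


def fit_logistic_design(
    X: pd.DataFrame, y: np.ndarray, maxiter: int = 100, tol: float = 1e-8
) -> FitResult:
    """Maximum-likelihood logistic fit on an explicit design matrix.

    Iteratively reweighted least squares, convergence on relative change
    below ``tol``; standard errors from the observed information; Wald 95%
    CIs.  Raises on rank deficiency (naming the collinear columns); flags
    terms at |coefficient| > 15 as likely separation.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must include both classes")
    Xv = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        # pinpoint columns whose removal restores full rank
        bad = []
        for j in range(Xv.shape[1]):
            keep = [i for i in range(Xv.shape[1]) if i != j]
            if np.linalg.matrix_rank(Xv[:, keep]) == rank:
                bad.append(X.columns[j])
        raise ValueError(f"design matrix is rank deficient; collinear terms: {bad}")

    model = sm.GLM(y, Xv, family=sm.families.Binomial())
    res = model.fit(maxiter=maxiter, tol=tol)
    names = list(X.columns)
    coefs = dict(zip(names, map(float, res.params)))
    ses = dict(zip(names, map(float, res.bse)))
    # np.exp: a separated term's CI degenerates to (0, inf) instead of raising
    with np.errstate(over="ignore"):
        ors = {k: float(np.exp(v)) for k, v in coefs.items()}
        ci = {
            k: (float(np.exp(coefs[k] - _Z95 * ses[k])),
                float(np.exp(coefs[k] + _Z95 * ses[k])))
            for k in names
        }
    flags = [k for k, v in coefs.items() if abs(v) > 15]
    return FitResult(
        coefficients=coefs,
        standard_errors=ses,
        odds_ratios=ors,
        ci95=ci,
        converged=bool(getattr(res, "converged", True)),
        n_obs=int(len(y)),
        log_likelihood=float(res.llf),
        separation_flags=flags,
    )


def _build_design(cohort: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    df = cohort
    X = pd.DataFrame(index=df.index)
    X["intercept"] = 1.0

    sexes = [s for s in sorted(df["sex"].unique()) if s != spec.reference_sex]
    for s in sexes:
        X[f"sex[{s}]"] = (df["sex"] == s).astype(float)

    age = df["age_at_dx"].to_numpy(dtype=float)
    knots = (
        np.asarray(spec.knots, dtype=float)
        if spec.knots is not None
        else default_knots(age, spec.n_knots)
    )
    basis = rcs_basis(age, knots)
    X["age"] = basis[:, 0]
    for j in range(1, basis.shape[1]):
        X[f"age_rcs{j}"] = basis[:, j]

    ref_h = spec.reference_hospital
    if ref_h is None:
        ref_h = df["hospital_id"].value_counts().idxmax()
    for level, ref, col in (
        ("cancer_group", spec.reference_group, "cancer_group"),
        ("hospital_id", ref_h, "hospital_id"),
    ):
        values = [v for v in sorted(df[col].unique()) if v != ref]
        if ref not in set(df[col].unique()):
            raise ValueError(f"reference level {ref!r} absent from {col}")
        for v in values:
            X[f"{col}[{v}]"] = (df[col] == v).astype(float)

    for c in ("n_mdt", "n_consult", "n_hosp"):
        X[c] = df[c].astype(float)
    if spec.include_metastatic:
        X["metastatic_at_dx"] = df["metastatic_at_dx"].astype(float)
    return X


def fit_logistic(spec: ModelSpec, cohort: pd.DataFrame) -> FitResult:
    """Fit the PS-documentation model described by ``spec`` on a cohort."""
    X = _build_design(cohort, spec)
    return fit_logistic_design(X, cohort["has_ps"].astype(float).to_numpy())


def compare_models(
    cohort: pd.DataFrame, spec: ModelSpec | None = None
) -> tuple[FitResult, FitResult, pd.DataFrame]:
    """Fit the model without and with metastatic status.

    Returns both fits plus a per-term table of the OR pair and their ratio,
    for inspecting how far adjustment moves the other associations.
    """
    base_spec = spec or ModelSpec()
    spec_a = ModelSpec(**{**base_spec.__dict__, "include_metastatic": False})
    spec_b = ModelSpec(**{**base_spec.__dict__, "include_metastatic": True})
    fit_a = fit_logistic(spec_a, cohort)
    fit_b = fit_logistic(spec_b, cohort)
    rows = []
    for term, or_a in fit_a.odds_ratios.items():
        or_b = fit_b.odds_ratios.get(term)
        rows.append(
            {
                "term": term,
                "or_without_metastatic": or_a,
                "or_with_metastatic": or_b,
                "or_ratio": (or_b / or_a) if or_b is not None else np.nan,
            }
        )
    return fit_a, fit_b, pd.DataFrame(rows)


def coefficient_table(fit: FitResult, model_variant: str) -> pd.DataFrame:
    """Long-format coefficient/OR table (forest-plot ready)."""
    rows = []
    for term in fit.coefficients:
        lo, hi = fit.ci95[term]
        rows.append(
            {
                "term": term,
                "estimate": fit.coefficients[term],
                "se": fit.standard_errors[term],
                "OR": fit.odds_ratios[term],
                "ci_low": lo,
                "ci_high": hi,
                "model_variant": model_variant,
            }
        )
    return pd.DataFrame(rows)
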