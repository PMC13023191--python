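"""Causal-effect estimators for a binary instrument, exposure and outcome.

Six estimators of the causal log-odds effect of X on Y instrumented by Z:

Wald ratios (instrument-outcome slope over instrument-exposure slope)
    ``wald_logistic``        ratio of logistic slopes gamma1 / alpha1
    ``wald_lpm``             ratio of linear-probability (OLS) slopes,
                             mapped back to the log-odds scale by the inverse
                             prevalence transformation
    ``wald_transformation``  logistic slopes mapped to the linear scale by
                             beta * pr * (1 - pr) before taking the ratio,
                             then mapped back

Instrumental-variable estimators
    ``estimate_sem``   logistic regression of Y on X (plus covariates); in the
                       all-binary setting a simultaneous two-equation system
                       has no cross-equation error term, so the joint ML fit
                       coincides with the two separate logistic fits
    ``estimate_tsps``  two-stage predictor substitution: Y regressed on the
                       first-stage fitted probability P_hat
    ``estimate_tsri``  two-stage residual inclusion: Y regressed on X and the
                       first-stage residual X - P_hat

All logistic stages share one maximum-likelihood kernel (:func:`fit_logistic`,
an IRLS/Newton scheme with step halving); all linear stages share
:func:`fit_lpm`.  Estimators never raise on a degenerate replicate: failed or
separated fits propagate as ``valid=False`` with a NaN estimate, never as a
silent zero.  User-input errors (constant response, zero-variance covariate
column) do raise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "GlmFit",
    "WaldEstimate",
    "CausalEstimate",
    "MREstimates",
    "DegenerateFitError",
    "RankDeficiencyError",
    "EstimationError",
    "fit_logistic",
    "fit_lpm",
    "transform_coefficient",
    "inverse_transform",
    "wald_logistic",
    "wald_lpm",
    "wald_transformation",
    "estimate_sem",
    "estimate_tsps",
    "estimate_tsri",
    "estimate_all",
    "ALPHA_MIN",
]

#: ratios with a first-stage slope below this magnitude are flagged invalid
ALPHA_MIN = 1e-8

#: a fitted coefficient larger than this on standardized data flags separation
SEPARATION_BOUND = 15.0

#: condition-number ceiling on the weighted normal matrix before a design is
#: treated as numerically rank-deficient
COND_MAX = 1e10


class EstimationError(ValueError):
    """Base class for estimation failures caused by the supplied data."""


class DegenerateFitError(EstimationError):
    """Response is constant (or otherwise uninformative) — no fit exists."""


class RankDeficiencyError(EstimationError):
    """Design matrix is rank deficient at the documented tolerance."""


# ---------------------------------------------------------------------------
# design-matrix plumbing

def _as_columns(design_columns) -> tuple[list[str], list[np.ndarray]]:
    """Accept a mapping name -> vector, or a pandas DataFrame."""
    if hasattr(design_columns, "columns"):  # DataFrame
        names = [str(c) for c in design_columns.columns]
        cols = [np.asarray(design_columns[c], dtype=float) for c in design_columns.columns]
    elif isinstance(design_columns, Mapping):
        names = [str(k) for k in design_columns]
        cols = [np.asarray(v, dtype=float) for v in design_columns.values()]
    else:
        raise TypeError("design_columns must be a mapping or a DataFrame")
    return names, cols


def _build_design(response, design_columns, add_intercept=True):
    y = np.asarray(response, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be binary 0/1")
    names, cols = _as_columns(design_columns)
    n = y.shape[0]
    for name, c in zip(names, cols):
        if c.shape[0] != n:
            raise ValueError(f"design column {name!r} length {c.shape[0]} != n {n}")
    if add_intercept:
        names = ["const"] + names
        cols = [np.ones(n)] + cols
    X = np.column_stack(cols) if cols else np.ones((n, 1))
    return y, X, names


def _check_covariates(covariates) -> dict[str, np.ndarray]:
    """Eager validation of user-supplied covariates (zero variance raises)."""
    if covariates is None:
        return {}
    names, cols = _as_columns(covariates)
    out: dict[str, np.ndarray] = {}
    for name, c in zip(names, cols):
        if np.ptp(c) == 0.0:
            raise RankDeficiencyError(
                f"covariate {name!r} is constant; design would be rank deficient"
            )
        out[name] = c
    return out


# ---------------------------------------------------------------------------
# fitting kernels

@dataclass
class GlmFit:
    """Coefficients and diagnostics of one regression stage."""

    names: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    fitted_values: np.ndarray
    converged: bool
    n_used: int

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.names.index(name)])

    def se(self, name: str) -> float:
        return float(self.standard_errors[self.names.index(name)])

    def params(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.coefficients)))


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # y*eta - log(1 + exp(eta)), overflow-safe
    return float(np.dot(y, eta) - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    response,
    design_columns,
    *,
    add_intercept: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> GlmFit:
    """Maximum-likelihood logistic regression via Newton/IRLS.

    Convergence is declared when the relative log-likelihood change falls
    below ``tol``; separation (non-convergence, or any coefficient exceeding
    15 on column-standardized scale) is reported as ``converged=False`` with
    the coefficients flagged invalid rather than raised, because downstream
    estimators must survive degenerate replicates.
    """
    y, X, names = _build_design(response, design_columns, add_intercept)
    n, p = X.shape
    if np.ptp(y) == 0.0:
        raise DegenerateFitError("response is constant; logistic fit is degenerate")

    beta = np.zeros(p)
    if add_intercept:
        pbar = min(max(y.mean(), 1e-6), 1 - 1e-6)
        beta[0] = np.log(pbar / (1 - pbar))

    eta = X @ beta
    ll = _loglik(y, eta)
    converged = False
    H = None
    for _ in range(max_iter):
        mu = expit(eta)
        w = mu * (1.0 - mu)
        H = (X * w[:, None]).T @ X
        # rank / conditioning check on the weighted normal matrix
        if not np.isfinite(H).all() or np.linalg.cond(H) > COND_MAX:
            raise RankDeficiencyError(
                "weighted design is numerically rank deficient "
                f"(cond > {COND_MAX:g})"
            )
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise RankDeficiencyError(str(exc)) from exc
        # Newton step with halving if the log-likelihood decreases
        ll_new = -np.inf
        for _half in range(30):
            beta_new = beta + step
            eta_new = X @ beta_new
            ll_new = _loglik(y, eta_new)
            if ll_new >= ll or not np.isfinite(ll_new):
                break
            step *= 0.5
        if not np.isfinite(ll_new):
            break
        beta, eta = beta_new, eta_new
        if abs(ll_new - ll) < tol * (abs(ll) + tol):
            ll = ll_new
            converged = True
            break
        ll = ll_new

    # separation heuristic: huge coefficients on standardized columns
    scale = X.std(axis=0)
    scale[scale == 0.0] = 1.0
    if converged and np.any(np.abs(beta[1:] if add_intercept else beta)
                            * (scale[1:] if add_intercept else scale)
                            > SEPARATION_BOUND):
        converged = False

    mu = expit(X @ beta)
    if converged and H is not None:
        try:
            cov = np.linalg.inv(H)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
    else:
        se = np.full(p, np.nan)
    return GlmFit(
        names=tuple(names),
        coefficients=beta,
        standard_errors=se,
        fitted_values=mu,
        converged=converged,
        n_used=n,
    )


def fit_lpm(response, design_columns, *, add_intercept: bool = True) -> GlmFit:
    """Linear probability model: ordinary least squares on a binary response.

    The slope on a single binary regressor equals the difference in group
    means of the response.
    """
    y, X, names = _build_design(response, design_columns, add_intercept)
    n, p = X.shape
    if np.ptp(y) == 0.0:
        raise DegenerateFitError("response is constant; LPM fit is degenerate")
    if np.linalg.matrix_rank(X) < p:
        raise RankDeficiencyError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    try:
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return GlmFit(
        names=tuple(names),
        coefficients=beta,
        standard_errors=se,
        fitted_values=fitted,
        converged=True,
        n_used=n,
    )


# ---------------------------------------------------------------------------
# prevalence transformation

def transform_coefficient(beta_logistic: float, pr: float) -> float:
    """Map a log-odds coefficient to the linear-probability scale.

    ``beta_linear = beta_logistic * pr * (1 - pr)`` where ``pr`` is the
    prevalence of the binary trait.
    """
    if not 0.0 < pr < 1.0:
        raise ValueError(f"pr must be in (0, 1), got {pr!r}")
    return beta_logistic * pr * (1.0 - pr)


def inverse_transform(beta_linear: float, pr: float) -> float:
    """Map a linear-probability coefficient back to the log-odds scale.

    Exact inverse of :func:`transform_coefficient` at the same ``pr``.
    """
    if not 0.0 < pr < 1.0:
        raise ValueError(f"pr must be in (0, 1), got {pr!r}")
    return beta_linear / (pr * (1.0 - pr))


# ---------------------------------------------------------------------------
# result containers

@dataclass
class WaldEstimate:
    """One Wald-ratio estimate on the log-odds scale."""

    method: str  # logistic | lpm | transformation
    estimate: float
    numerator: float = np.nan
    denominator: float = np.nan
    pr_x: Optional[float] = None
    pr_y: Optional[float] = None
    valid: bool = True


@dataclass
class CausalEstimate:
    """One instrumental-variable estimate on the log-odds scale."""

    method: str  # sem | tsps | tsri
    estimate: float
    residual_coefficient: Optional[float] = None
    first_stage: Optional[GlmFit] = None
    second_stage: Optional[GlmFit] = None
    valid: bool = True


def _invalid_wald(method: str, **kw) -> WaldEstimate:
    return WaldEstimate(method=method, estimate=np.nan, valid=False, **kw)


def _invalid_causal(method: str, **kw) -> CausalEstimate:
    return CausalEstimate(method=method, estimate=np.nan, valid=False, **kw)


def _zxy(data) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Accept a Dataset-like object with Z/X/Y attributes or a 3-tuple."""
    if hasattr(data, "Z"):
        Z, X, Y = data.Z, data.X, data.Y
    else:
        Z, X, Y = data
    Z = np.asarray(Z, dtype=float)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if not (Z.shape == X.shape == Y.shape):
        raise ValueError("Z, X, Y must share the same length")
    for name, v in (("Z", Z), ("X", X), ("Y", Y)):
        if not np.isin(v, (0.0, 1.0)).all():
            raise ValueError(f"{name} must be binary 0/1")
    return Z, X, Y


# ---------------------------------------------------------------------------
# internal builders shared by the one-shot functions and estimate_all

def _wald_logistic_from(fx: GlmFit, fy: GlmFit) -> WaldEstimate:
    if not (fx.converged and fy.converged):
        return _invalid_wald("logistic")
    a1, g1 = fx.coef("Z"), fy.coef("Z")
    if abs(a1) < ALPHA_MIN:
        return _invalid_wald("logistic", numerator=g1, denominator=a1)
    return WaldEstimate("logistic", g1 / a1, numerator=g1, denominator=a1)


def _wald_lpm_from(fx: GlmFit, fy: GlmFit, pr_y: float) -> WaldEstimate:
    if not (fx.converged and fy.converged):
        return _invalid_wald("lpm")
    a1, g1 = fx.coef("Z"), fy.coef("Z")
    if abs(a1) < ALPHA_MIN or not 0.0 < pr_y < 1.0:
        return _invalid_wald("lpm", numerator=g1, denominator=a1, pr_y=pr_y)
    est = inverse_transform(g1 / a1, pr_y)
    return WaldEstimate("lpm", est, numerator=g1, denominator=a1, pr_y=pr_y)


def _wald_transformation_from(
    fx: GlmFit, fy: GlmFit, pr_x: float, pr_y: float
) -> WaldEstimate:
    if not (fx.converged and fy.converged):
        return _invalid_wald("transformation")
    if not (0.0 < pr_x < 1.0 and 0.0 < pr_y < 1.0):
        return _invalid_wald("transformation", pr_x=pr_x, pr_y=pr_y)
    a_lin = transform_coefficient(fx.coef("Z"), pr_x)
    g_lin = transform_coefficient(fy.coef("Z"), pr_y)
    if abs(a_lin) < ALPHA_MIN:
        return _invalid_wald(
            "transformation", numerator=g_lin, denominator=a_lin,
            pr_x=pr_x, pr_y=pr_y,
        )
    est = inverse_transform(g_lin / a_lin, pr_y)
    return WaldEstimate(
        "transformation", est, numerator=g_lin, denominator=a_lin,
        pr_x=pr_x, pr_y=pr_y,
    )


def _fit_or_none(fitfun, y, cols):
    try:
        return fitfun(y, cols)
    except EstimationError:
        return None


# ---------------------------------------------------------------------------
# public estimators

def wald_logistic(data, covariates=None) -> WaldEstimate:
    """Wald ratio from two logistic regressions on the instrument."""
    Z, X, Y = _zxy(data)
    cov = _check_covariates(covariates)
    fx = _fit_or_none(fit_logistic, X, {"Z": Z, **cov})
    fy = _fit_or_none(fit_logistic, Y, {"Z": Z, **cov})
    if fx is None or fy is None:
        return _invalid_wald("logistic")
    return _wald_logistic_from(fx, fy)


def wald_lpm(data, covariates=None) -> WaldEstimate:
    """Wald ratio from two linear probability models, inverse-transformed
    onto the log-odds scale with the sample prevalence of the outcome."""
    Z, X, Y = _zxy(data)
    cov = _check_covariates(covariates)
    fx = _fit_or_none(fit_lpm, X, {"Z": Z, **cov})
    fy = _fit_or_none(fit_lpm, Y, {"Z": Z, **cov})
    if fx is None or fy is None:
        return _invalid_wald("lpm")
    return _wald_lpm_from(fx, fy, float(Y.mean()))


def wald_transformation(data, covariates=None) -> WaldEstimate:
    """Wald ratio from logistic slopes mapped to the linear scale by the
    prevalence transformation, then back to the log-odds scale."""
    Z, X, Y = _zxy(data)
    cov = _check_covariates(covariates)
    fx = _fit_or_none(fit_logistic, X, {"Z": Z, **cov})
    fy = _fit_or_none(fit_logistic, Y, {"Z": Z, **cov})
    if fx is None or fy is None:
        return _invalid_wald("transformation")
    return _wald_transformation_from(fx, fy, float(X.mean()), float(Y.mean()))


def estimate_sem(data, covariates=None) -> CausalEstimate:
    """Structural-equation estimate: logistic Y on X (plus covariates).

    With binary responses there is no cross-equation error term to correlate,
    so simultaneous and sequential maximum likelihood coincide; the exposure
    equation is fitted alongside for reporting.
    """
    Z, X, Y = _zxy(data)
    cov = _check_covariates(covariates)
    first = _fit_or_none(fit_logistic, X, {"Z": Z, **cov})
    second = _fit_or_none(fit_logistic, Y, {"X": X, **cov})
    if second is None or not second.converged:
        return _invalid_causal("sem", first_stage=first, second_stage=second)
    return CausalEstimate(
        "sem", second.coef("X"), first_stage=first, second_stage=second
    )


def estimate_tsps(data, covariates=None) -> CausalEstimate:
    """Two-stage predictor substitution: logistic Y on the first-stage
    fitted probability of exposure."""
    Z, X, Y = _zxy(data)
    cov = _check_covariates(covariates)
    first = _fit_or_none(fit_logistic, X, {"Z": Z, **cov})
    if first is None or not first.converged:
        return _invalid_causal("tsps", first_stage=first)
    second = _fit_or_none(
        fit_logistic, Y, {"P_hat": first.fitted_values, **cov}
    )
    if second is None or not second.converged:
        return _invalid_causal("tsps", first_stage=first, second_stage=second)
    return CausalEstimate(
        "tsps", second.coef("P_hat"), first_stage=first, second_stage=second
    )


def estimate_tsri(data, covariates=None) -> CausalEstimate:
    """Two-stage residual inclusion: logistic Y on X and the first-stage
    residual X - P_hat; the estimate is the coefficient on X."""
    Z, X, Y = _zxy(data)
    cov = _check_covariates(covariates)
    first = _fit_or_none(fit_logistic, X, {"Z": Z, **cov})
    if first is None or not first.converged:
        return _invalid_causal("tsri", first_stage=first)
    resid = X - first.fitted_values
    second = _fit_or_none(
        fit_logistic, Y, {"X": X, "resid": resid, **cov}
    )
    if second is None or not second.converged:
        return _invalid_causal("tsri", first_stage=first, second_stage=second)
    return CausalEstimate(
        "tsri",
        second.coef("X"),
        residual_coefficient=second.coef("resid"),
        first_stage=first,
        second_stage=second,
    )


@dataclass
class MREstimates:
    """All six estimates computed on one dataset with shared stage fits."""

    wald: dict[str, WaldEstimate] = field(default_factory=dict)
    iv: dict[str, CausalEstimate] = field(default_factory=dict)
    n: int = 0
    pr_x: float = np.nan
    pr_y: float = np.nan

    def bias_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(3, 3) array of iv - wald differences and a validity mask;
        rows sem/tsps/tsri, columns logistic/lpm/transformation."""
        from .bias_study import IV_METHODS, WALD_METHODS, compute_bias

        bias = np.full((3, 3), np.nan)
        valid = np.zeros((3, 3), dtype=bool)
        for i, ivm in enumerate(IV_METHODS):
            for j, wm in enumerate(WALD_METHODS):
                a, b = self.iv[ivm], self.wald[wm]
                if a.valid and b.valid:
                    bias[i, j] = compute_bias(a.estimate, b.estimate)
                    valid[i, j] = True
        return bias, valid


def estimate_all(data, covariates=None) -> MREstimates:
    """Run all six estimators, reusing shared regression stages.

    The logistic first stage X ~ Z is fitted once and reused by the logistic
    and transformation Wald ratios, TSPS and TSRI; Y ~ Z is shared by the two
    logistic-based Wald ratios.  Results are identical to calling the six
    one-shot functions individually (same kernels, same data).
    """
    Z, X, Y = _zxy(data)
    cov = _check_covariates(covariates)
    pr_x, pr_y = float(X.mean()), float(Y.mean())

    fx_log = _fit_or_none(fit_logistic, X, {"Z": Z, **cov})
    fy_log = _fit_or_none(fit_logistic, Y, {"Z": Z, **cov})
    fx_lin = _fit_or_none(fit_lpm, X, {"Z": Z, **cov})
    fy_lin = _fit_or_none(fit_lpm, Y, {"Z": Z, **cov})

    out = MREstimates(n=len(Z), pr_x=pr_x, pr_y=pr_y)

    if fx_log is None or fy_log is None:
        out.wald["logistic"] = _invalid_wald("logistic")
        out.wald["transformation"] = _invalid_wald("transformation")
    else:
        out.wald["logistic"] = _wald_logistic_from(fx_log, fy_log)
        out.wald["transformation"] = _wald_transformation_from(
            fx_log, fy_log, pr_x, pr_y
        )
    if fx_lin is None or fy_lin is None:
        out.wald["lpm"] = _invalid_wald("lpm")
    else:
        out.wald["lpm"] = _wald_lpm_from(fx_lin, fy_lin, pr_y)

    # SEM: logistic Y ~ X
    sem_fit = _fit_or_none(fit_logistic, Y, {"X": X, **cov})
    if sem_fit is None or not sem_fit.converged:
        out.iv["sem"] = _invalid_causal("sem", first_stage=fx_log, second_stage=sem_fit)
    else:
        out.iv["sem"] = CausalEstimate(
            "sem", sem_fit.coef("X"), first_stage=fx_log, second_stage=sem_fit
        )

    # TSPS / TSRI share the logistic first stage
    if fx_log is None or not fx_log.converged:
        out.iv["tsps"] = _invalid_causal("tsps", first_stage=fx_log)
        out.iv["tsri"] = _invalid_causal("tsri", first_stage=fx_log)
        return out

    tsps_fit = _fit_or_none(fit_logistic, Y, {"P_hat": fx_log.fitted_values, **cov})
    if tsps_fit is None or not tsps_fit.converged:
        out.iv["tsps"] = _invalid_causal("tsps", first_stage=fx_log, second_stage=tsps_fit)
    else:
        out.iv["tsps"] = CausalEstimate(
            "tsps", tsps_fit.coef("P_hat"), first_stage=fx_log, second_stage=tsps_fit
        )

    resid = X - fx_log.fitted_values
    tsri_fit = _fit_or_none(fit_logistic, Y, {"X": X, "resid": resid, **cov})
    if tsri_fit is None or not tsri_fit.converged:
        out.iv["tsri"] = _invalid_causal("tsri", first_stage=fx_log, second_stage=tsri_fit)
    else:
        out.iv["tsri"] = CausalEstimate(
            "tsri",
            tsri_fit.coef("X"),
            residual_coefficient=tsri_fit.coef("resid"),
            first_stage=fx_log,
            second_stage=tsri_fit,
        )
    return out
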