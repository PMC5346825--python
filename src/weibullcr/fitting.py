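"""Cause-specific Weibull regression with competing risks.

Model
-----
Each cause of death j = 1..K has a Weibull cause-specific hazard

    h_j(t | x) = lambda_j(x) * p_j * t^(p_j - 1),    lambda_j(x) = exp(x . beta_j)

so the cause-specific survival function is S_j(t|x) = exp(-lambda_j(x) t^p_j)
and overall survival is the product over causes.  The log link on the scale
makes each cause a proportional-hazards model: exp(beta) is a time-constant
hazard ratio.  The shape p_j is cause-specific and covariate-free.

The full-data log-likelihood over subjects i with observed time t_i and
event code d_i (0 = censored) is

    l = sum_i [ sum_j 1{d_i=j} log h_j(t_i, x_i)  -  sum_j lambda_j(x_i) t_i^p_j ]

which separates into independent per-cause terms: the competing-risks fit
for cause j is exactly a single-event Weibull fit with all other causes
treated as censored.  Fitting exploits this, maximising each cause's term
by quasi-Newton optimisation over (beta_j, log p_j) with analytic
gradients; standard errors come from the inverse of the numerically
differentiated observed information at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy import optimize, stats

from .data_model import DESIGN_COLUMNS, Dataset, design_matrix

Z_975 = 1.959964  # 97.5% standard-normal quantile used for 95% Wald CIs

EventDefinition = Literal["cause-1-only", "any-death"]


@dataclass
class ModelParams:
    """Per-cause coefficient vectors and shapes.

    ``betas`` has shape (K, d) with the intercept first; ``shapes`` holds
    the K Weibull shape parameters p_j (> 0).
    """

    betas: np.ndarray
    shapes: np.ndarray

    def __post_init__(self) -> None:
        self.betas = np.atleast_2d(np.asarray(self.betas, dtype=float))
        self.shapes = np.atleast_1d(np.asarray(self.shapes, dtype=float))
        if self.betas.shape[0] != self.shapes.shape[0]:
            raise ValueError("betas and shapes must agree on the number of causes")
        if np.any(self.shapes <= 0):
            raise ValueError("shapes must be strictly positive")

    @property
    def n_causes(self) -> int:
        return self.betas.shape[0]

    def scale(self, x: np.ndarray, j: int) -> float:
        """lambda_j(x) = exp(x . beta_j); causes are 1-based."""
        return float(np.exp(np.asarray(x, dtype=float) @ self.betas[j - 1]))


def cause_specific_hazard(t, x: np.ndarray, j: int, params: ModelParams):
    """Cause-specific hazard h_j(t|x) = lambda_j p_j t^(p_j-1), per month."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("hazard requires t > 0")
    lam = params.scale(x, j)
    p = params.shapes[j - 1]
    return lam * p * t ** (p - 1.0)


def cause_specific_survival(t, x: np.ndarray, j: int, params: ModelParams):
    """S_j(t|x) = exp(-lambda_j(x) t^p_j)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("survival requires t >= 0")
    lam = params.scale(x, j)
    return np.exp(-lam * t ** params.shapes[j - 1])


def overall_survival(t, x: np.ndarray, params: ModelParams):
    """All-cause survival: exp(-sum_j lambda_j t^p_j) = prod_j S_j(t|x)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("survival requires t >= 0")
    cumhaz = sum(
        params.scale(x, j) * t ** params.shapes[j - 1]
        for j in range(1, params.n_causes + 1)
    )
    return np.exp(-cumhaz)


def log_likelihood(dataset: Dataset, params: ModelParams) -> float:
    """Competing-risks Weibull log-likelihood of the cohort.

    Additively separable across causes; other-cause events contribute only
    through their survival (censoring-like) term for cause j.
    """
    if params.n_causes < dataset.n_causes:
        raise ValueError("params cover fewer causes than the dataset declares")
    t = dataset.times
    if np.any(t <= 0):
        raise ValueError("all times must be positive")
    d = dataset.events
    X = design_matrix(dataset)
    total = 0.0
    for j in range(1, params.n_causes + 1):
        total += _loglik_single(t, (d == j).astype(float), X, params.betas[j - 1],
                                np.log(params.shapes[j - 1]))
    return float(total)


# clamps keep wild line-search iterates finite; inactive near any optimum
_LOG_CUMHAZ_CAP = 500.0
_LOGP_CAP = 30.0


def _loglik_single(t, delta, X, beta, logp) -> float:
    p = np.exp(min(logp, _LOGP_CAP))
    eta = X @ beta
    logt = np.log(t)
    cumhaz = np.exp(np.minimum(eta + p * logt, _LOG_CUMHAZ_CAP))
    return float(np.sum(delta * (eta + logp + (p - 1.0) * logt) - cumhaz))


def _grad_single(t, delta, X, beta, logp) -> np.ndarray:
    """Analytic gradient of the single-cause log-likelihood wrt (beta, log p)."""
    p = np.exp(min(logp, _LOGP_CAP))
    logt = np.log(t)
    cumhaz = np.exp(np.minimum(X @ beta + p * logt, _LOG_CUMHAZ_CAP))
    g_beta = X.T @ (delta - cumhaz)
    g_logp = p * np.sum(delta * (1.0 / p + logt) - cumhaz * logt)
    return np.concatenate([g_beta, [g_logp]])


@dataclass
class CauseSpecificFit:
    """MLE result for one cause: estimates, covariance and convergence state.

    ``covariance`` is for the working parameter (beta, log p); the leading
    d x d block gives coefficient standard errors directly.
    """

    cause: int
    beta: np.ndarray
    shape: float
    covariance: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    n_events: int
    estimable: bool = True
    message: str = ""
    design_columns: tuple[str, ...] = DESIGN_COLUMNS

    @property
    def beta_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance)[: len(self.beta)])

    @property
    def params(self) -> ModelParams:
        return ModelParams(betas=self.beta[None, :], shapes=np.array([self.shape]))

    def to_dict(self) -> dict:
        return {
            "cause": self.cause,
            "design_columns": list(self.design_columns),
            "beta": self.beta.tolist(),
            "beta_se": self.beta_se.tolist(),
            "shape": self.shape,
            "covariance": self.covariance.tolist(),
            "loglik": self.loglik,
            "converged": bool(self.converged),
            "n_iter": self.n_iter,
            "n_events": self.n_events,
            "estimable": bool(self.estimable),
            "message": self.message,
        }


def _numerical_hessian(fun, x0: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of a scalar function (observed information
    is the negated Hessian of the log-likelihood)."""
    d = len(x0)
    H = np.zeros((d, d))
    hs = eps * np.maximum(1.0, np.abs(x0))
    for i in range(d):
        for k in range(i, d):
            ei = np.zeros(d); ei[i] = hs[i]
            ek = np.zeros(d); ek[k] = hs[k]
            f_pp = fun(x0 + ei + ek)
            f_pm = fun(x0 + ei - ek)
            f_mp = fun(x0 - ei + ek)
            f_mm = fun(x0 - ei - ek)
            H[i, k] = H[k, i] = (f_pp - f_pm - f_mp + f_mm) / (4.0 * hs[i] * hs[k])
    return H

GRADIENT_TOL = 1e-5  # sup-norm of the scaled gradient required at a solution
_MAX_RESTARTS = 4


def _scaled_gradient_norm(g, theta, f) -> float:
    """Sup-norm of the gradient in relative units: change of the objective
    per relative parameter change, relative to the objective's magnitude —
    invariant to covariate and sample-size scale."""
    return float(np.max(np.abs(g) * np.maximum(1.0, np.abs(theta)))
                 / max(1.0, abs(f)))


def _fit_single_cause(
    t: np.ndarray,
    delta: np.ndarray,
    X: np.ndarray,
    cause: int,
    rng: np.random.Generator | None = None,
    fixed_shape: float | None = None,
) -> CauseSpecificFit:
    n_events = int(delta.sum())
    d = X.shape[1]
    if n_events == 0:
        return CauseSpecificFit(
            cause=cause, beta=np.full(d, np.nan), shape=np.nan,
            covariance=np.full((d + 1, d + 1), np.nan), loglik=np.nan,
            converged=False, n_iter=0, n_events=0, estimable=False,
            message="no events of this cause; fit not estimable",
        )
    if np.linalg.matrix_rank(X) < d:
        return CauseSpecificFit(
            cause=cause, beta=np.full(d, np.nan), shape=np.nan,
            covariance=np.full((d + 1, d + 1), np.nan), loglik=np.nan,
            converged=False, n_iter=0, n_events=n_events, estimable=False,
            message="design matrix is rank deficient",
        )

    logp_fixed = None if fixed_shape is None else float(np.log(fixed_shape))
    n_free = d + 1 if logp_fixed is None else d

    def negll(theta):
        if logp_fixed is None:
            return -_loglik_single(t, delta, X, theta[:-1], theta[-1])
        return -_loglik_single(t, delta, X, theta, logp_fixed)

    def neggrad(theta):
        if logp_fixed is None:
            return -_grad_single(t, delta, X, theta[:-1], theta[-1])
        return -_grad_single(t, delta, X, theta, logp_fixed)[:-1]

    # Exponential closed-form MLE seeds the intercept: events / person-time.
    x0 = np.zeros(n_free)
    x0[0] = np.log(n_events / t.sum())
    rng = rng or np.random.default_rng(0)

    def _polish(theta):
        # Newton steps from the quasi-Newton solution push the gradient to
        # (near) machine precision; step-halving guards ascent.
        for _ in range(20):
            g = neggrad(theta)
            if _scaled_gradient_norm(g, theta, negll(theta)) < GRADIENT_TOL / 100:
                break
            H = _numerical_hessian(negll, theta)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                break
            f0 = negll(theta)
            alpha = 1.0
            while alpha > 1e-4 and negll(theta - alpha * step) > f0:
                alpha /= 2.0
            if negll(theta - alpha * step) > f0:
                break
            theta = theta - alpha * step
        return theta

    best_x = None
    best_f = np.inf
    n_iter = 0
    for attempt in range(_MAX_RESTARTS + 1):
        start = x0 if attempt == 0 else x0 + rng.normal(scale=0.3, size=n_free)
        res = optimize.minimize(negll, start, jac=neggrad, method="BFGS",
                                options={"maxiter": 500, "gtol": 1e-9})
        n_iter += res.nit
        x_pol = _polish(res.x)
        f_pol = negll(x_pol)
        if f_pol < best_f:
            best_f, best_x = f_pol, x_pol
        if _scaled_gradient_norm(neggrad(best_x), best_x, best_f) < GRADIENT_TOL:
            break

    theta = best_x
    converged = bool(
        _scaled_gradient_norm(neggrad(theta), theta, best_f) < GRADIENT_TOL
    )
    info = _numerical_hessian(negll, theta)
    try:
        cov_free = np.linalg.inv(info)
        cov_ok = np.all(np.diag(cov_free) > 0)
    except np.linalg.LinAlgError:
        cov_free = np.full((n_free, n_free), np.nan)
        cov_ok = False
    # covariance is always (d+1, d+1) for (beta, log p); zero row/col when
    # the shape was held fixed
    cov = np.zeros((d + 1, d + 1))
    cov[:n_free, :n_free] = cov_free
    message = "" if converged and cov_ok else (
        "optimizer did not reach gradient tolerance" if not converged
        else "observed information not invertible / not positive definite"
    )
    beta_hat = theta.copy() if logp_fixed is not None else theta[:-1].copy()
    shape_hat = fixed_shape if logp_fixed is not None else float(np.exp(theta[-1]))
    return CauseSpecificFit(
        cause=cause, beta=beta_hat, shape=shape_hat,
        covariance=cov, loglik=float(-best_f), converged=converged and cov_ok,
        n_iter=n_iter, n_events=n_events, estimable=True, message=message,
        design_columns=tuple(DESIGN_COLUMNS[:d]) if d <= len(DESIGN_COLUMNS)
        else tuple(f"x{i}" for i in range(d)),
    )


def fit_competing(
    dataset: Dataset,
    design: np.ndarray | None = None,
    seed: int = 0,
    fixed_shape: float | None = None,
) -> list[CauseSpecificFit]:
    """Fit the competing-risks Weibull model: one cause-specific fit per
    cause, each maximising its own separable likelihood term.

    A cause with zero observed events is returned flagged non-estimable;
    the other causes are unaffected.  ``fixed_shape`` holds every p_j at a
    known value (1.0 gives the exponential sub-model) instead of
    estimating it.
    """
    t = dataset.times
    if np.any(t <= 0):
        raise ValueError("all times must be positive")
    X = design if design is not None else design_matrix(dataset)
    d_codes = dataset.events
    rng = np.random.default_rng(seed)
    return [
        _fit_single_cause(t, (d_codes == j).astype(float), X, cause=j, rng=rng,
                          fixed_shape=fixed_shape)
        for j in range(1, dataset.n_causes + 1)
    ]


def fit_naive(
    dataset: Dataset,
    design: np.ndarray | None = None,
    event_definition: EventDefinition = "cause-1-only",
    seed: int = 0,
    fixed_shape: float | None = None,
) -> CauseSpecificFit:
    """Single-event Weibull fit ignoring the competing-risks structure.

    ``"cause-1-only"`` treats cause-1 deaths as events and everything else
    (censoring and competing deaths alike) as censored — the standard
    "ignore competing risks" analysis.  ``"any-death"`` pools all causes
    into one event.
    """
    t = dataset.times
    if np.any(t <= 0):
        raise ValueError("all times must be positive")
    X = design if design is not None else design_matrix(dataset)
    d_codes = dataset.events
    if event_definition == "cause-1-only":
        delta = (d_codes == 1).astype(float)
    elif event_definition == "any-death":
        delta = (d_codes > 0).astype(float)
    else:
        raise ValueError(f"unknown event definition {event_definition!r}")
    return _fit_single_cause(t, delta, X, cause=1, rng=np.random.default_rng(seed),
                             fixed_shape=fixed_shape)


class HazardRatio(NamedTuple):
    hr: float
    ci_low: float
    ci_high: float
    p_value: float


def wald_interval(coef: float, se: float, z: float = Z_975) -> tuple[float, float]:
    """95% Wald CI for a hazard ratio: exponentiated coefficient endpoints."""
    return float(np.exp(coef - z * se)), float(np.exp(coef + z * se))


def wald_p_value(coef: float, se: float) -> float:
    """Two-sided Wald p-value of coef/SE against the standard normal."""
    return float(2.0 * stats.norm.sf(abs(coef) / se))


def hr_from_coefficient(coef: float, se: float) -> HazardRatio:
    """HR, 95% CI and two-sided p-value from a coefficient and its SE."""
    lo, hi = wald_interval(coef, se)
    return HazardRatio(float(np.exp(coef)), lo, hi, wald_p_value(coef, se))


def hazard_ratio(fit: CauseSpecificFit, covariate: str) -> HazardRatio:
    """Wald inference for one covariate of a converged cause-specific fit."""
    if covariate not in fit.design_columns:
        raise KeyError(f"unknown covariate {covariate!r}; have {fit.design_columns}")
    if not fit.estimable:
        raise ValueError(f"cause {fit.cause} fit is not estimable: {fit.message}")
    i = fit.design_columns.index(covariate)
    return hr_from_coefficient(float(fit.beta[i]), float(fit.beta_se[i]))
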