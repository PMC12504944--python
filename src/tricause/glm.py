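"""Internal GLM core: logistic and linear fits with delta-method marginal effects.

All estimators in :mod:`tricause.estimators` are built on these two model
families.  The logistic solver is iteratively reweighted least squares with a
deviance-based stopping rule; the coefficient covariance is the inverse of the
observed information (the inverse Hessian).  Average marginal effects (AMEs)
and their standard errors are computed by the delta method through that
covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

MAX_ITER = 100
DEVIANCE_TOL = 1e-8


class ConvergenceError(RuntimeError):
    """Raised when a fit does not converge (e.g. perfect separation)."""

    def __init__(self, message: str, terms: list[str] | None = None):
        super().__init__(message)
        self.terms = terms or []


@dataclass
class FittedModel:
    """A fitted regression model.

    Parameters are keyed by term name; ``cov`` is the coefficient covariance
    (inverse Hessian for the logistic family, sigma^2 (X'X)^-1 for the linear
    family).
    """

    family: str                      # "logistic" or "linear"
    term_names: list[str]
    params: np.ndarray
    cov: np.ndarray
    n_obs: int
    converged: bool = True
    deviance: float = np.nan
    n_iter: int = 0
    diagnostics: dict = field(default_factory=dict)

    @property
    def coef(self) -> dict[str, float]:
        return dict(zip(self.term_names, self.params))

    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def linpred(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.params

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Mean response: probabilities for logistic, linear predictor else."""
        eta = self.linpred(X)
        if self.family == "logistic":
            return special.expit(eta)
        return eta

    def wald(self, term: str) -> float:
        """Squared Wald z statistic for one term (single-coefficient F)."""
        j = self.term_names.index(term)
        return float((self.params[j] / np.sqrt(self.cov[j, j])) ** 2)


def fit_glm(
    X: np.ndarray,
    y: np.ndarray,
    term_names: list[str],
    family: str = "logistic",
    max_iter: int = MAX_ITER,
    tol: float = DEVIANCE_TOL,
) -> FittedModel:
    """Fit a logistic (IRLS) or linear (OLS) regression.

    Raises
    ------
    ConvergenceError
        If the IRLS loop exhausts ``max_iter`` or the working weights
        degenerate (perfect separation); the error names the terms with the
        largest coefficients, which are typically the offending ones.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if len(term_names) != p:
        raise ValueError("term_names length does not match design columns")

    if family == "linear":
        params, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < p:
            raise ConvergenceError(
                f"rank-deficient linear design (rank {rank} < {p})", term_names
            )
        resid = y - X @ params
        dof = max(n - p, 1)
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        return FittedModel("linear", list(term_names), params, cov, n,
                           deviance=float(resid @ resid))

    if family != "logistic":
        raise ValueError(f"unknown family {family!r}")

    beta = np.zeros(p)
    dev_old = np.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta
        prob = special.expit(eta)
        w = prob * (1.0 - prob)
        if np.min(w) < 1e-10:
            # fitted probabilities pinned at 0/1: quasi-separation
            worst = _largest_terms(term_names, beta)
            raise ConvergenceError(
                "perfect or quasi-perfect separation detected "
                f"(suspect terms: {', '.join(worst)})", worst,
            )
        XtW = X.T * w
        try:
            beta = np.linalg.solve(XtW @ X, XtW @ (eta + (y - prob) / w))
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"singular information matrix: {exc}", list(term_names)
            ) from exc
        prob = special.expit(X @ beta)
        dev = -2.0 * float(
            np.sum(y * np.log(np.clip(prob, 1e-300, None))
                   + (1 - y) * np.log(np.clip(1 - prob, 1e-300, None)))
        )
        if abs(dev - dev_old) < tol:
            w = prob * (1.0 - prob)
            if np.min(w) < 1e-10:
                worst = _largest_terms(term_names, beta)
                raise ConvergenceError(
                    "perfect or quasi-perfect separation detected "
                    f"(suspect terms: {', '.join(worst)})", worst,
                )
            cov = np.linalg.inv((X.T * w) @ X)
            return FittedModel("logistic", list(term_names), beta, cov, n,
                               deviance=dev, n_iter=it)
        dev_old = dev
    worst = _largest_terms(term_names, beta)
    raise ConvergenceError(
        f"IRLS did not converge in {max_iter} iterations "
        f"(suspect terms: {', '.join(worst)})", worst,
    )


def _largest_terms(term_names: list[str], beta: np.ndarray, k: int = 2) -> list[str]:
    order = np.argsort(-np.abs(beta))
    return [term_names[i] for i in order[:k]]


def ame_contrast(
    fit: FittedModel,
    X_hi: np.ndarray,
    X_lo: np.ndarray,
    signs: np.ndarray | None = None,
) -> tuple[float, float]:
    """Average contrast of predicted means between two (stacks of) designs.

    The estimate is ``mean(signs * (mu(X_hi) - mu(X_lo)))`` where ``mu`` is
    the mean response of the fitted model; its SE comes from the delta method
    through the coefficient covariance.  For a binary treatment term this is
    the average marginal effect on the risk-difference scale; with
    ``signs=(+1,-1)`` stacks it expresses difference-in-difference contrasts.
    """
    X_hi = np.asarray(X_hi, dtype=float)
    X_lo = np.asarray(X_lo, dtype=float)
    n = X_hi.shape[0]
    if signs is None:
        signs = np.ones(n)
    signs = np.asarray(signs, dtype=float)

    if fit.family == "linear":
        diff = (X_hi - X_lo) @ fit.params
        grad = (signs[:, None] * (X_hi - X_lo)).mean(axis=0)
    else:
        eta_hi = X_hi @ fit.params
        eta_lo = X_lo @ fit.params
        p_hi = special.expit(eta_hi)
        p_lo = special.expit(eta_lo)
        diff = p_hi - p_lo
        d_hi = p_hi * (1 - p_hi)
        d_lo = p_lo * (1 - p_lo)
        grad = (signs[:, None] * (d_hi[:, None] * X_hi - d_lo[:, None] * X_lo)
                ).mean(axis=0)
    est = float(np.mean(signs * diff))
    var = float(grad @ fit.cov @ grad)
    return est, float(np.sqrt(max(var, 0.0)))


def wald_test(est: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """Two-sided Wald p-value and symmetric CI bounds for one estimate."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    if se <= 0:
        return np.nan, est, est
    p = 2.0 * stats.norm.sf(abs(est) / se)
    return float(p), float(est - z * se), float(est + z * se)
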