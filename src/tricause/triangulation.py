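"""Dissimilarity testing for sets of correlated effect estimates.

Different causal estimators applied to the same patients are correlated, so
comparing them with independent-sample heterogeneity tests is misleading.
This module implements a generalized Cochran's-Q statistic

    Q_e = (b - b_ivw)' S^{-1} (b - b_ivw)

where ``b`` is the vector of estimates in the set ``e``, ``b_ivw`` their
inverse-variance-weighted average, and ``S`` the estimates' covariance
matrix approximated by a non-parametric bootstrap (refitting every method on
each resample of the data).  Under the null that all estimates target the
same quantity, Q_e is asymptotically chi-square with ``len(e) - 1`` degrees
of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import as_frame, fit_method
from .simulate import derive_seed

CONDITION_CAP = 1e10
MAX_FAILED_FRACTION = 0.10


class SingularCovarianceError(np.linalg.LinAlgError):
    """Bootstrap covariance too ill-conditioned for a stable Q statistic."""


@dataclass
class BootstrapCovariance:
    """Bootstrap covariance of a set of estimators plus the replicate draws."""

    methods: list[str]
    cov: np.ndarray
    replicates: pd.DataFrame      # one row per successful resample
    n_failed: int
    B: int
    seed: int
    resample: str = "patient"

    @property
    def correlation(self) -> np.ndarray:
        sd = np.sqrt(np.diag(self.cov))
        return self.cov / np.outer(sd, sd)


@dataclass
class DissimilarityResult:
    """Q_e heterogeneity test over a set of (correlated) effect estimates."""

    methods: list[str]
    beta_vec: np.ndarray
    weights: np.ndarray
    ivw: float
    cov: np.ndarray
    q_stat: float
    df: int
    p_value: float
    alpha: float = 0.05
    B: int | None = None
    seed: int | None = None
    n_failed: int = 0
    diagnostics: dict = field(default_factory=dict)

    @property
    def reject(self) -> bool:
        return bool(self.p_value < self.alpha)

    def to_dict(self) -> dict:
        return {
            "methods": list(self.methods),
            "beta_vec": [float(b) for b in self.beta_vec],
            "ivw": float(self.ivw),
            "cov": [[float(v) for v in row] for row in self.cov],
            "q_stat": float(self.q_stat),
            "df": int(self.df),
            "p_value": float(self.p_value),
            "alpha": float(self.alpha),
            "reject": self.reject,
            "B": self.B,
            "seed": self.seed,
            "failed_resamples": int(self.n_failed),
        }

    def summary(self) -> str:
        lines = [
            f"dissimilarity test over {{{', '.join(self.methods)}}}",
            "-" * 48,
            "estimates : " + ", ".join(f"{b:.4f}" for b in self.beta_vec),
            f"IVW pool  : {self.ivw:.4f}",
            f"Q statistic: {self.q_stat:.3f} on {self.df} df",
            f"p-value   : {self.p_value:.4g}"
            f"  ({'reject' if self.reject else 'no rejection'} at "
            f"alpha={self.alpha:g})",
        ]
        if self.B is not None:
            lines.append(f"bootstrap : B={self.B}, {self.n_failed} failed resamples")
        return "\n".join(lines)


def ivw_average(beta_vec, variances) -> float:
    """Inverse-variance-weighted average of a vector of estimates."""
    beta_vec = np.asarray(beta_vec, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if np.any(variances <= 0):
        raise ValueError("all variances must be strictly positive")
    w = 1.0 / variances
    return float(w @ beta_vec / w.sum())


def bootstrap_covariance(
    data,
    methods: list[str],
    B: int = 500,
    seed: int = 0,
    resample: str = "patient",
    method_kwargs: dict | None = None,
) -> BootstrapCovariance:
    """Empirical covariance of method estimates over bootstrap resamples.

    Each resample redraws ``n`` patients with replacement (or, with
    ``resample="cluster"``, whole provider clusters — relevant because the
    instrument is cluster-constant) and refits every method.  Resamples on
    which any method fails to converge are dropped and counted; more than
    10% failures is an error.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    if resample not in ("patient", "cluster"):
        raise ValueError("resample must be 'patient' or 'cluster'")
    frame = as_frame(data)
    n = len(frame)
    kwargs = method_kwargs or {}
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    clusters = frame["cluster_id"].to_numpy()
    unique_clusters = np.unique(clusters)

    rows = []
    n_failed = 0
    for b in range(B):
        if resample == "patient":
            idx = rng.integers(0, n, n)
        else:
            picked = rng.choice(unique_clusters, size=len(unique_clusters),
                                replace=True)
            idx = np.concatenate([np.flatnonzero(clusters == g) for g in picked])
        boot = frame.iloc[idx].reset_index(drop=True)
        boot["patient_id"] = np.arange(len(boot))  # unique ids for matching
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = [fit_method(m, boot, seed=derive_seed(seed, b),
                                  **kwargs.get(m, {})).beta_hat
                       for m in methods]
        except Exception:
            n_failed += 1
            continue
        rows.append(est)

    if n_failed > MAX_FAILED_FRACTION * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap resamples failed to converge; "
            "covariance estimate unreliable"
        )
    reps = pd.DataFrame(rows, columns=list(methods))
    cov = np.cov(reps.to_numpy(), rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    return BootstrapCovariance(list(methods), cov, reps, n_failed, B, seed,
                               resample)


def q_statistic(beta_vec, cov, alpha: float = 0.05) -> DissimilarityResult:
    """Generalized Cochran's Q for correlated estimates.

    The IVW pool uses the diagonal of ``cov`` as the per-estimate variances,
    so weights and the quadratic-form covariance are internally consistent.
    An ill-conditioned covariance (condition number above 1e10) is an error:
    a near-singular covariance (e.g. from near-duplicate methods) makes the
    statistic unstable, and no silent pseudo-inverse is taken.
    """
    beta_vec = np.asarray(beta_vec, dtype=float)
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    k = beta_vec.size
    if k < 2:
        raise ValueError("need at least two estimates to compare")
    if cov.shape != (k, k):
        raise ValueError(f"covariance shape {cov.shape} does not match {k} estimates")
    variances = np.diag(cov)
    if np.any(variances <= 0):
        raise ValueError("covariance diagonal must be strictly positive")
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > CONDITION_CAP:
        raise SingularCovarianceError(
            f"estimate covariance is ill-conditioned (cond={cond:.3g}); "
            "drop one of the near-collinear methods from the set"
        )
    weights = 1.0 / variances
    pooled = ivw_average(beta_vec, variances)
    resid = beta_vec - pooled
    q = float(resid @ np.linalg.solve(cov, resid))
    df = k - 1
    p = float(stats.chi2.sf(q, df))
    return DissimilarityResult(
        methods=[f"est{i}" for i in range(k)], beta_vec=beta_vec,
        weights=weights, ivw=pooled, cov=cov, q_stat=q, df=df, p_value=p,
        alpha=alpha,
    )


class Triangulation:
    """Model-style interface: estimates, bootstrap covariance and Q_e in one go.

    Parameters
    ----------
    data : AnalyticDataset or DataFrame
    methods : list of registry labels (see ``tricause.estimators.METHODS``)
    B : bootstrap replicates for the covariance (default 500)
    resample : "patient" (default) or "cluster"
    """

    def __init__(self, data, methods: list[str], B: int = 500, seed: int = 0,
                 alpha: float = 0.05, resample: str = "patient",
                 method_kwargs: dict | None = None):
        if len(methods) < 2:
            raise ValueError("need at least two methods to triangulate")
        self.data = as_frame(data)
        self.methods = list(methods)
        self.B = B
        self.seed = seed
        self.alpha = alpha
        self.resample = resample
        self.method_kwargs = method_kwargs or {}

    def fit(self) -> DissimilarityResult:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            point = [fit_method(m, self.data, seed=derive_seed(self.seed, 1 << 20),
                                **self.method_kwargs.get(m, {}))
                     for m in self.methods]
        boot = bootstrap_covariance(
            self.data, self.methods, B=self.B, seed=self.seed,
            resample=self.resample, method_kwargs=self.method_kwargs,
        )
        result = q_statistic(np.array([r.beta_hat for r in point]), boot.cov,
                             self.alpha)
        result.methods = [r.method for r in point]
        result.B = self.B
        result.seed = self.seed
        result.n_failed = boot.n_failed
        if boot.n_failed:
            result.diagnostics["failed_resamples"] = boot.n_failed
        result.diagnostics["resample"] = self.resample
        return result
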