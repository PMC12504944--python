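"""Two-period observational data generator with known causal ground truth.

The generator emulates a comparative-effectiveness cohort: ``n`` patients
nested in ``n_g`` equally sized provider clusters, a binary provider-level
preference instrument ``Z``, continuous measured confounders ``W0``/``W1``
(prior / study period), one standard-normal unmeasured confounder ``U``,
binary outcomes ``Y0`` (prior period) and ``Y1`` (study period), and a binary
treatment ``X`` chosen at the start of the study period.

Outcome models are specified on the probability scale with an additive
treatment effect, so the true estimand — the average causal risk difference
``E[Y1(1)] - E[Y1(0)]`` — equals ``beta`` exactly up to probability clamping.
Both potential study-period outcomes are stored so the truth can be recovered
from any simulated sample; these oracle columns (and ``u``) are never used by
the estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .scenarios import ScenarioConfig

#: Columns every analytic dataset must carry, in canonical order.
CORE_COLUMNS = ["patient_id", "cluster_id", "z", "x", "y0", "y1", "w0", "w1"]
#: Simulator-only ground-truth columns, firewalled from all estimators.
ORACLE_COLUMNS = ["u", "y1_po_1", "y1_po_0"]


class CalibrationError(RuntimeError):
    """Raised when a scenario's coefficients clamp too many probabilities."""


@dataclass
class AnalyticDataset:
    """Per-patient analytic records wrapped around a pandas DataFrame."""

    frame: pd.DataFrame
    config: ScenarioConfig | None = None

    def __post_init__(self):
        validate_frame(self.frame)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def has_oracle(self) -> bool:
        return all(c in self.frame.columns for c in ORACLE_COLUMNS)

    def public(self) -> pd.DataFrame:
        """The estimator-visible view: oracle columns stripped."""
        return self.frame[CORE_COLUMNS].copy()

    def subset(self, idx) -> "AnalyticDataset":
        """Row subset / resample (positional indices); keeps oracle columns."""
        return AnalyticDataset(self.frame.iloc[idx].reset_index(drop=True),
                               config=self.config)

    def true_risk_difference(self) -> float:
        """Sample-average causal risk difference from the stored potential outcomes."""
        if not self.has_oracle:
            raise ValueError("dataset carries no oracle columns")
        return float((self.frame["y1_po_1"] - self.frame["y1_po_0"]).mean())


def validate_frame(frame: pd.DataFrame) -> None:
    missing = [c for c in CORE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"dataset is missing required columns: {missing}")
    for col in ("z", "x", "y0", "y1"):
        vals = frame[col].to_numpy()
        if not np.isin(vals, (0, 1)).all():
            bad = int(np.flatnonzero(~np.isin(vals, (0, 1)))[0])
            raise ValueError(f"column {col!r} is not binary (first bad row: {bad})")
    z_per_cluster = frame.groupby("cluster_id")["z"].nunique()
    bad = z_per_cluster[z_per_cluster > 1]
    if len(bad):
        raise ValueError(
            "instrument z varies within cluster(s) "
            f"{list(bad.index[:5])}; z must be provider-constant"
        )


def _clamp(p: np.ndarray, eps: float) -> tuple[np.ndarray, np.ndarray]:
    """Clamp probabilities into [eps, 1-eps]; also return the clamped mask."""
    clipped = np.clip(p, eps, 1.0 - eps)
    return clipped, (p < eps) | (p > 1.0 - eps)


def simulate_dataset(config: ScenarioConfig, seed: int) -> AnalyticDataset:
    """Draw one dataset under ``config``; same (config, seed) -> identical data.

    Generation order is fixed: cluster-level Z, then per-patient U, W0, W1,
    Y0, X, and finally both potential outcomes Y1(0)/Y1(1) coupled through a
    single uniform draw per patient (so Y1(1) >= Y1(0) whenever beta >= 0).

    Raises
    ------
    CalibrationError
        If more than ``config.clamp_tol`` of patients need probability
        clamping in any outcome or treatment model — a sign the coefficients
        are miscalibrated for a rare-event design.
    """
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    c = config.coef
    n, n_g = config.n, config.n_g
    eps = config.prob_floor
    size = config.cluster_size

    cluster_id = np.repeat(np.arange(n_g), size)
    z_cluster = (rng.random(n_g) < c["z_prev"]).astype(np.int8)
    z = z_cluster[cluster_id]

    u = rng.standard_normal(n)
    w0 = rng.standard_normal(n)
    rho = c["w_rho"]
    w1 = rho * w0 + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)

    # prior-period outcome (probability scale)
    p0 = c["y0_int"] + c["y0_w0"] * w0
    if config.y0_confounded:
        p0 = p0 + c["y0_u"] * u
    p0, clamped0 = _clamp(p0, eps)
    y0 = (rng.random(n) < p0).astype(np.int8)

    # treatment (log-odds scale)
    eta = c["x_int"] + c["x_z"] * z + c["x_w1"] * w1
    if config.did1_violated:
        eta = eta + c["x_y0"] * y0
    if config.nuc_violated:
        eta = eta + c["x_u"] * u
    if config.poa_relevance:
        eta = eta + c["x_y0z"] * y0 * z
    x = (rng.random(n) < special.expit(eta)).astype(np.int8)

    # study-period potential outcomes (probability scale, additive beta)
    q_base = c["y1_int"] + c["y1_w1"] * w1
    if config.nuc_violated:
        q_base = q_base + c["y1_u"] * u
    if config.iv2_violated:
        q_base = q_base + c["y1_z"] * z
    if config.y0_direct:
        q_base = q_base + c["y1_y0"] * y0
    q0, clamped_a = _clamp(q_base, eps)
    q1, clamped_b = _clamp(q_base + config.beta, eps)
    draw = rng.random(n)
    y1_po_0 = (draw < q0).astype(np.int8)
    y1_po_1 = (draw < q1).astype(np.int8)
    y1 = np.where(x == 1, y1_po_1, y1_po_0).astype(np.int8)

    for name, mask in (("prior outcome", clamped0),
                       ("study outcome", clamped_a | clamped_b)):
        frac = float(mask.mean())
        if frac > config.clamp_tol:
            raise CalibrationError(
                f"{frac:.1%} of patients had the {name} probability clamped "
                f"(tolerance {config.clamp_tol:.1%}); coefficients are "
                "miscalibrated for this design"
            )

    frame = pd.DataFrame({
        "patient_id": np.arange(n),
        "cluster_id": cluster_id,
        "z": z, "x": x, "y0": y0, "y1": y1,
        "w0": w0, "w1": w1,
        "u": u, "y1_po_1": y1_po_1, "y1_po_0": y1_po_0,
    })
    return AnalyticDataset(frame, config=config)


def true_effect(config: ScenarioConfig, n_mc: int = 200_000, seed: int = 0) -> float:
    """Monte-Carlo estimate of the average causal risk difference.

    Simulates a fresh sample of ``n_mc`` patients (cluster count scaled to
    keep the configured cluster size) and averages ``Y1(1) - Y1(0)``.  Equals
    ``config.beta`` in expectation whenever no clamping occurs.
    """
    if n_mc < 10_000:
        raise ValueError("n_mc must be at least 10,000")
    size = config.cluster_size
    n = (n_mc // size) * size
    cfg = config.with_overrides(n=n, n_g=n // size)
    return simulate_dataset(cfg, seed).true_risk_difference()


def derive_seed(master_seed: int, index: int) -> int:
    """Replicate seed scheme: child ``index`` of ``master_seed``.

    Deterministic, collision-free across indices, and always below 2**31 so
    the result can be passed anywhere a small integer seed is expected.
    """
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
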