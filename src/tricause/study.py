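"""Monte-Carlo study orchestration and preference-instrument construction.

``run_simulation_study`` repeats simulate-and-fit over replicates and
summarizes each (scenario, method) cell with bias, empirical SE, MSE,
95%-CI coverage and type-1 error, each with its Monte-Carlo standard error
(Morris-style reporting).  ``run_qtest_study`` does the analogous experiment
for the bootstrap Q dissimilarity test, reporting rejection rates with Wald
binomial intervals.  ``build_preference_iv`` derives a provider-preference
instrument from longitudinal prescribing records: each patient's instrument
is the treatment their provider chose for the previous patient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import fit_method
from .scenarios import ScenarioConfig
from .simulate import derive_seed, simulate_dataset
from .triangulation import Triangulation

METRICS = ("bias", "emp_se", "mse", "coverage", "t1e")


@dataclass
class PerformanceSummary:
    """Long-format (scenario, method, metric) table of study results."""

    table: pd.DataFrame          # scenario, method, metric, value, mcse
    n_reps: int
    truth: float
    estimates: pd.DataFrame      # per-replicate estimates for audit

    def cell(self, scenario: str, method: str) -> dict:
        sub = self.table[(self.table["scenario"] == scenario)
                         & (self.table["method"] == method)]
        return {r.metric: (r.value, r.mcse) for r in sub.itertuples()}

    def value(self, scenario: str, method: str, metric: str) -> float:
        return self.cell(scenario, method)[metric][0]

    def pivot(self, metric: str) -> pd.DataFrame:
        sub = self.table[self.table["metric"] == metric]
        return sub.pivot(index="scenario", columns="method", values="value")


def performance_metrics(estimates, ses, cis, pvals, truth: float) -> dict:
    """Bias/empirical-SE/MSE/coverage/T1E with Monte-Carlo SEs for one cell.

    ``cis`` is a sequence of (low, high) pairs.  MCSEs follow the standard
    simulation-study formulas: bias MCSE = empSE/sqrt(R); empSE MCSE =
    empSE/sqrt(2(R-1)); MSE MCSE = SD(squared errors)/sqrt(R); proportions
    use sqrt(p(1-p)/R).
    """
    est = np.asarray(estimates, dtype=float)
    ses = np.asarray(ses, dtype=float)
    cis = np.asarray(cis, dtype=float).reshape(-1, 2)
    pvals = np.asarray(pvals, dtype=float)
    R = est.size
    if not (ses.size == R and cis.shape[0] == R and pvals.size == R):
        raise ValueError("metric input vectors have mismatched lengths")
    if R < 2:
        raise ValueError("need at least 2 replicates")

    err = est - truth
    bias = float(err.mean())
    emp_se = float(est.std(ddof=1))
    mse = float((err**2).mean())
    cover = float(((cis[:, 0] <= truth) & (truth <= cis[:, 1])).mean())
    t1e = float((pvals < 0.05).mean())
    return {
        "bias": (bias, emp_se / np.sqrt(R)),
        "emp_se": (emp_se, emp_se / np.sqrt(2.0 * (R - 1))),
        "mse": (mse, float((err**2).std(ddof=1)) / np.sqrt(R)),
        "coverage": (cover, float(np.sqrt(cover * (1 - cover) / R))),
        "t1e": (t1e, float(np.sqrt(t1e * (1 - t1e) / R))),
        "mean_se": (float(ses.mean()), float(ses.std(ddof=1) / np.sqrt(R))),
    }


def scenario_method_kwargs(config: ScenarioConfig, strict: bool = False) -> dict:
    """Scenario-appropriate adjustment sets for each estimator.

    Unless ``strict``, the instrument is included as a measured confounder in
    the confounder-adjustment and difference-in-difference models whenever
    the exclusion restriction is violated (it then confounds the study
    outcome), and the prior outcome enters the single-period outcome models
    whenever it directly affects the study outcome.
    """
    if strict:
        return {}
    kw: dict[str, dict] = {}
    if config.iv2_violated:
        kw["cat"] = {"include_z": True}
        kw["did"] = {"include_z": True}
    if config.y0_direct:
        for m in ("cat", "psm", "iv", "cf"):
            kw.setdefault(m, {})["include_y0"] = True
    return kw


def run_simulation_study(
    configs,
    methods: list[str],
    n_reps: int = 500,
    master_seed: int = 0,
    null_truth: bool = False,
    strict: bool = False,
) -> PerformanceSummary:
    """Monte-Carlo performance study over scenarios and estimators.

    With ``null_truth`` the scenarios are re-simulated at zero treatment
    effect (for type-1-error assessment) and metrics are computed against a
    truth of 0.  Failed fits are recorded per method and the replicate is
    kept for the other methods; more than 5% failures in a cell raises.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    if isinstance(configs, ScenarioConfig):
        configs = [configs]
    records = []
    rows = []
    for s_idx, config in enumerate(configs):
        if null_truth:
            config = config.with_overrides(beta=0.0)
        truth = config.beta
        kwargs = scenario_method_kwargs(config, strict)
        collected: dict[str, list] = {m: [] for m in methods}
        for rep in range(n_reps):
            seed = derive_seed(master_seed, s_idx * n_reps + rep)
            data = simulate_dataset(config, seed)
            for m in methods:
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        r = fit_method(m, data, seed=seed, **kwargs.get(m, {}))
                except Exception:
                    collected[m].append(None)
                    continue
                collected[m].append(r)
                records.append({
                    "scenario": config.scenario_id, "method": m, "rep": rep,
                    "beta_hat": r.beta_hat, "se": r.se,
                    "ci_low": r.ci_low, "ci_high": r.ci_high,
                    "p_value": r.p_value,
                })
        for m in methods:
            fits = [r for r in collected[m] if r is not None]
            n_failed = n_reps - len(fits)
            if n_failed > 0.05 * n_reps:
                raise RuntimeError(
                    f"method {m!r} failed on {n_failed}/{n_reps} replicates "
                    f"under scenario {config.scenario_id!r}"
                )
            cell = performance_metrics(
                [r.beta_hat for r in fits], [r.se for r in fits],
                [(r.ci_low, r.ci_high) for r in fits],
                [r.p_value for r in fits], truth,
            )
            for metric, (value, mcse) in cell.items():
                rows.append({
                    "scenario": config.scenario_id, "method": m,
                    "metric": metric, "value": value, "mcse": mcse,
                    "n_reps": n_reps - n_failed, "n_failed": n_failed,
                })
    table = pd.DataFrame(rows)
    return PerformanceSummary(table, n_reps, truth,
                              pd.DataFrame(records))


def run_qtest_study(
    config: ScenarioConfig,
    method_pairs: list[tuple[str, str]],
    n_reps: int = 100,
    B: int = 200,
    master_seed: int = 0,
    alpha: float = 0.05,
    strict: bool = False,
) -> pd.DataFrame:
    """Rejection rate of the Q dissimilarity test over simulated replicates.

    Returns one row per method pair with the rejection rate at ``alpha`` and
    a Wald 95% binomial confidence interval.
    """
    if n_reps < 50:
        raise ValueError("n_reps must be at least 50")
    if B < 100:
        raise ValueError("B must be at least 100")
    kwargs = scenario_method_kwargs(config, strict)
    rejections = {pair: [] for pair in method_pairs}
    for rep in range(n_reps):
        seed = derive_seed(master_seed, rep)
        data = simulate_dataset(config, seed)
        for pair in method_pairs:
            result = Triangulation(
                data, list(pair), B=B, seed=seed, alpha=alpha,
                method_kwargs={m: kwargs.get(m, {}) for m in pair},
            ).fit()
            rejections[pair].append(result.reject)
    rows = []
    z = stats.norm.ppf(0.975)
    for pair, flags in rejections.items():
        rate = float(np.mean(flags))
        half = z * np.sqrt(rate * (1 - rate) / len(flags))
        rows.append({
            "scenario": config.scenario_id,
            "pair": " + ".join(pair),
            "rejection_rate": rate,
            "ci_low": max(0.0, rate - half),
            "ci_high": min(1.0, rate + half),
            "n_reps": len(flags), "B": B, "alpha": alpha,
        })
    return pd.DataFrame(rows)


def build_preference_iv(records: pd.DataFrame, window: int = 1) -> pd.Series:
    """Provider-preference instrument from longitudinal prescribing records.

    ``records`` needs columns ``provider_id, patient_id, order_index,
    treatment``.  Within each provider, patient ``k``'s instrument is the
    treatment of the provider's previous patient (``order_index k-1``); with
    ``window > 1`` it is the majority of the last ``window`` prescriptions
    (ties resolve to 1).  The first patient of each provider has no history
    and is excluded from the returned map.
    """
    if window < 1:
        raise ValueError("window must be at least 1")
    required = {"provider_id", "patient_id", "order_index", "treatment"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records are missing columns: {sorted(missing)}")
    out: dict = {}
    for provider, grp in records.groupby("provider_id"):
        if grp["order_index"].duplicated().any():
            raise ValueError(
                f"duplicate order_index within provider {provider!r}"
            )
        grp = grp.sort_values("order_index")
        tx = grp["treatment"].to_numpy(float)
        pid = grp["patient_id"].to_numpy()
        for k in range(1, len(grp)):
            recent = tx[max(0, k - window):k]
            out[pid[k]] = int(recent.mean() >= 0.5)
    return pd.Series(out, name="z", dtype=int)
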