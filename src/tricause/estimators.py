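"""Treatment-effect estimators on the risk-difference scale.

Seven estimation strategies for a binary treatment ``x`` and binary
study-period outcome ``y1``, each exposed as a small model class whose
``fit()`` returns an :class:`EffectResults`:

=============  ==========================================================
``CaT``        confounder-adjusted outcome regression ("corrected as
               treated"); unbiased under no unmeasured confounding
``PSMatch``    the same estimate on a 1-1 propensity-matched subset
``TwoStageIV`` two-stage instrumental-variable estimator: logistic
               treatment model, predicted treatment plugged into the
               outcome model
``ControlFunction``  IV variant for binary outcomes entering the
               first-stage residual (and its instrument interaction)
``DiD``        difference-in-difference over the prior and study periods
               via a single stacked regression
``PriorOutcomeIV``/``PriorOutcomeCF``  prior-outcome-augmented IV/CF,
               using the prior-outcome-by-instrument interaction as a
               new instrument while controlling for direct instrument
               and prior-outcome effects
=============  ==========================================================

Every estimate is reported as a proportion-scale risk difference with a
delta-method standard error, Wald confidence interval and two-sided p-value.
Standard errors condition on the first stage (the estimation noise of the
treatment model is deliberately not propagated); a patient-level bootstrap
alternative lives in :mod:`tricause.triangulation`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import FittedModel, ame_contrast, fit_glm, wald_test
from .simulate import AnalyticDataset, CORE_COLUMNS

WEAK_F_THRESHOLD = 10.0


class WeakInstrumentWarning(UserWarning):
    """Instrument's first-stage F-statistic is below the usual threshold of 10."""


@dataclass
class EffectResults:
    """One method's causal risk-difference estimate with inference."""

    method: str
    beta_hat: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    level: float = 0.95
    diagnostics: dict = field(default_factory=dict)
    model: FittedModel | None = None   # final-stage fit

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "beta_hat": self.beta_hat,
            "se": self.se,
            "ci": [self.ci_low, self.ci_high],
            "p_value": self.p_value,
            "n_used": self.n_used,
            "level": self.level,
            "diagnostics": {k: v for k, v in self.diagnostics.items()
                            if np.isscalar(v) or isinstance(v, (bool, str))},
        }

    def summary(self, percent: bool = False) -> str:
        s = 100.0 if percent else 1.0
        unit = "%" if percent else ""
        lines = [
            f"{self.method} risk-difference estimate",
            "-" * 40,
            f"estimate : {self.beta_hat * s: .4f}{unit}",
            f"std err  : {self.se * s: .4f}{unit}",
            f"{self.level:.0%} CI   : [{self.ci_low * s: .4f}, {self.ci_high * s: .4f}]{unit}",
            f"p-value  : {self.p_value: .3g}",
            f"n used   : {self.n_used}",
        ]
        for k, v in self.diagnostics.items():
            if np.isscalar(v):
                lines.append(f"{k:9s}: {v}")
        return "\n".join(lines)


def as_frame(data) -> pd.DataFrame:
    """Estimator-visible frame; strips oracle columns from simulated data."""
    if isinstance(data, AnalyticDataset):
        return data.public()
    frame = pd.DataFrame(data)
    missing = [c for c in CORE_COLUMNS if c not in frame.columns
               and c not in ("patient_id", "cluster_id")]
    if missing:
        raise ValueError(f"dataset is missing required columns: {missing}")
    return frame.reset_index(drop=True)


def build_design(frame: pd.DataFrame, terms: list[str]) -> np.ndarray:
    """Design matrix from term names: ``const``, columns, and ``a:b`` products."""
    n = len(frame)
    cols = []
    for t in terms:
        if t == "const":
            cols.append(np.ones(n))
        elif ":" in t:
            a, b = t.split(":")
            cols.append(frame[a].to_numpy(float) * frame[b].to_numpy(float))
        else:
            cols.append(frame[t].to_numpy(float))
    return np.column_stack(cols)


def ame(fit: FittedModel, data, target_term: str) -> tuple[float, float]:
    """Average marginal effect of moving ``target_term`` from 0 to 1.

    All other covariates (including any interaction involving the target)
    are held at their observed values; the SE is by the delta method through
    the final-stage coefficient covariance.
    """
    frame = data if isinstance(data, pd.DataFrame) else as_frame(data)
    if target_term not in fit.term_names:
        raise ValueError(f"{target_term!r} is not a term of the fitted model")
    obs = frame[target_term].to_numpy(float)
    if obs.min() < 0.0 or obs.max() > 1.0:
        raise ValueError(
            f"target term {target_term!r} is not binary/probability-valued; "
            "a 0-to-1 contrast is not meaningful"
        )
    hi = frame.copy()
    lo = frame.copy()
    hi[target_term] = 1.0
    lo[target_term] = 0.0
    X_hi = build_design(hi, fit.term_names)
    X_lo = build_design(lo, fit.term_names)
    return ame_contrast(fit, X_hi, X_lo)


def _results(method, est, se, n, level, diagnostics, model) -> EffectResults:
    p, lo, hi = wald_test(est, se, level)
    return EffectResults(method, float(est), float(se), lo, hi, p, int(n),
                         level, diagnostics, model)


# ---------------------------------------------------------------------------
# model classes
# ---------------------------------------------------------------------------

class EffectModel:
    """Base class: construct from data, ``fit()`` returns :class:`EffectResults`."""

    method = "?"

    def __init__(self, data, level: float = 0.95):
        self.frame = as_frame(data)
        self.level = level

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "EffectModel":
        return cls(frame, **kwargs)

    def fit(self) -> EffectResults:  # pragma: no cover - abstract
        raise NotImplementedError


class CaT(EffectModel):
    """Confounder-adjusted ("corrected as treated") outcome regression.

    Logistic regression of the study outcome on treatment and the measured
    study-period confounder, optionally also on the instrument (when the
    exclusion restriction fails the instrument is itself a measured
    confounder) and on the prior outcome.  The estimate is the AME of
    treatment.
    """

    method = "CaT"

    def __init__(self, data, include_z: bool = False, include_y0: bool = False,
                 family: str = "logistic", covariates: tuple = ("w1",),
                 level: float = 0.95):
        super().__init__(data, level)
        self.include_z = include_z
        self.include_y0 = include_y0
        self.family = family
        self.covariates = tuple(covariates)
        if include_z:
            self.method = "CaT+Z"

    def terms(self) -> list[str]:
        t = ["const", "x", *self.covariates]
        if self.include_z:
            t.append("z")
        if self.include_y0:
            t.append("y0")
        return t

    def fit(self) -> EffectResults:
        terms = self.terms()
        m = fit_glm(build_design(self.frame, terms),
                    self.frame["y1"].to_numpy(float), terms, self.family)
        est, se = ame(m, self.frame, "x")
        return _results(self.method, est, se, len(self.frame), self.level,
                        {"converged": m.converged}, m)


class PSMatch(EffectModel):
    """Outcome regression on a 1-1 nearest-neighbour propensity-matched subset.

    Greedy matching on the logistic propensity score, without replacement and
    with no caliper by default; treated patients are processed in a seeded
    random order and distance ties go to the lowest patient id.
    """

    method = "PSM"

    def __init__(self, data, include_y0: bool = False,
                 caliper: float | None = None, seed: int = 0,
                 level: float = 0.95):
        super().__init__(data, level)
        self.include_y0 = include_y0
        self.caliper = caliper
        self.seed = seed

    def propensity_terms(self) -> list[str]:
        # zero-variance covariates carry no information and would make the
        # propensity design singular; drop them
        covs = [c for c in ["w1"] + (["y0"] if self.include_y0 else [])
                if self.frame[c].nunique() > 1]
        return ["const"] + covs


    def fit(self) -> EffectResults:
        frame = self.frame
        terms = self.propensity_terms()
        x = frame["x"].to_numpy(int)
        if x.sum() < 2 or (1 - x).sum() < 2:
            raise ValueError("need at least 2 patients in each treatment arm")
        ps_model = fit_glm(build_design(frame, terms),
                           frame["x"].to_numpy(float), terms)
        score = ps_model.predict(build_design(frame, terms))

        treated = np.flatnonzero(x == 1)
        control = np.flatnonzero(x == 0)
        rng = np.random.default_rng(self.seed)
        order = treated[rng.permutation(len(treated))]
        pid = frame["patient_id"].to_numpy()

        used = np.zeros(len(control), dtype=bool)
        pairs: list[tuple[int, int]] = []
        for t_idx in order:
            free = np.flatnonzero(~used)
            if free.size == 0:
                break
            d = np.abs(score[control[free]] - score[t_idx])
            m = d.min()
            if self.caliper is not None and m > self.caliper:
                continue
            cand = free[d == m]
            pick = cand[np.argmin(pid[control[cand]])]
            used[pick] = True
            pairs.append((t_idx, control[pick]))
        if not pairs:
            raise ValueError("propensity matching produced an empty matched set")

        idx = np.concatenate([[t, c] for t, c in pairs])
        matched = frame.iloc[idx].reset_index(drop=True)

        covs = ["w1"] + (["y0"] if self.include_y0 else [])
        diagnostics = {
            "n_pairs": len(pairs),
            "matched_fraction": 2 * len(pairs) / len(frame),
        }
        for c in covs:
            diagnostics[f"smd_pre_{c}"] = _smd(frame, c)
            diagnostics[f"smd_post_{c}"] = _smd(matched, c)

        covs = tuple(c for c in ("w1",) if matched[c].nunique() > 1)
        sub = CaT(matched, include_y0=self.include_y0, covariates=covs,
                  level=self.level).fit()
        diagnostics["converged"] = sub.diagnostics["converged"]
        res = _results(self.method, sub.beta_hat, sub.se, len(matched),
                       self.level, diagnostics, sub.model)
        return res


def _smd(frame: pd.DataFrame, col: str) -> float:
    a = frame.loc[frame["x"] == 1, col].to_numpy(float)
    b = frame.loc[frame["x"] == 0, col].to_numpy(float)
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    return float((a.mean() - b.mean()) / pooled) if pooled > 0 else 0.0


def _first_stage(frame: pd.DataFrame, augmented: bool,
                 include_y0: bool = False,
                 covariates: tuple = ("w1",)) -> FittedModel:
    if augmented:
        terms = ["const", "z", *covariates, "y0", "y0:z"]
    else:
        terms = ["const", "z", *covariates] + (["y0"] if include_y0 else [])
    return fit_glm(build_design(frame, terms), frame["x"].to_numpy(float), terms)


def first_stage_f(data, instrument: str = "z", include_y0: bool = False) -> float:
    """Single-instrument F: squared Wald z of the instrument's coefficient.

    ``instrument="z"`` uses the plain treatment model (X ~ Z + W1);
    ``instrument="y0z"`` uses the augmented model (X ~ Z + W1 + Y0 + Y0*Z)
    and reports the interaction term's statistic.
    """
    frame = as_frame(data)
    if instrument == "z":
        return _first_stage(frame, augmented=False, include_y0=include_y0).wald("z")
    if instrument == "y0z":
        return _first_stage(frame, augmented=True).wald("y0:z")
    raise ValueError("instrument must be 'z' or 'y0z'")


def _warn_weak(f: float, name: str) -> None:
    if f < WEAK_F_THRESHOLD:
        warnings.warn(
            f"weak instrument: first-stage F for {name} is {f:.2f} < "
            f"{WEAK_F_THRESHOLD:g}; the estimate may be unstable",
            WeakInstrumentWarning, stacklevel=3,
        )


class TwoStageIV(EffectModel):
    """Two-stage instrumental-variable estimator.

    Stage 1: logistic treatment model on the instrument and confounder.
    Stage 2: outcome model (logistic by default, linear optional) on the
    predicted treatment probability and confounder; the estimate is the AME
    of moving the predicted treatment from 0 to 1.
    """

    method = "IV"
    augmented = False

    def __init__(self, data, include_y0: bool = False,
                 second_stage: str = "logistic", covariates: tuple = ("w1",),
                 level: float = 0.95):
        super().__init__(data, level)
        self.include_y0 = include_y0
        self.second_stage = second_stage
        self.covariates = tuple(covariates)

    def _stage1(self) -> FittedModel:
        return _first_stage(self.frame, self.augmented, self.include_y0,
                            self.covariates)

    def _stage2_terms(self) -> list[str]:
        return ["const", "xhat", *self.covariates] + (
            ["y0"] if self.include_y0 else [])

    def fit(self) -> EffectResults:
        s1 = self._stage1()
        diagnostics = {"first_stage_f_z": s1.wald("z"), "converged": True}
        _warn_weak(diagnostics["first_stage_f_z"], "z")
        work = self.frame.copy()
        s1_terms = s1.term_names
        work["xhat"] = s1.predict(build_design(work, s1_terms))
        terms = self._stage2_terms()
        s2 = fit_glm(build_design(work, terms), work["y1"].to_numpy(float),
                     terms, self.second_stage)
        est, se = ame(s2, work, "xhat")
        return _results(self.method, est, se, len(work), self.level,
                        diagnostics, s2)


class ControlFunction(TwoStageIV):
    """Control-function IV estimator for binary outcomes.

    The first-stage residual (observed minus predicted treatment) and its
    interaction with the instrument enter the outcome model alongside the
    observed treatment; the estimate is the AME of treatment.
    """

    method = "CF"

    def fit(self) -> EffectResults:
        s1 = self._stage1()
        diagnostics = {"first_stage_f_z": s1.wald("z"), "converged": True}
        _warn_weak(diagnostics["first_stage_f_z"], "z")
        work = self.frame.copy()
        work["delta"] = work["x"].to_numpy(float) - s1.predict(
            build_design(work, s1.term_names))
        terms = (["const", "x", *self.covariates]
                 + (["y0"] if self.include_y0 else [])
                 + ["delta", "delta:z"])
        s2 = fit_glm(build_design(work, terms), work["y1"].to_numpy(float),
                     terms, "logistic")
        est, se = ame(s2, work, "x")
        return _results(self.method, est, se, len(work), self.level,
                        diagnostics, s2)


class PriorOutcomeIV(TwoStageIV):
    """Prior-outcome-augmented IV.

    The treatment model additionally includes the prior outcome and the
    prior-outcome-by-instrument interaction (the new instrument); the outcome
    model controls for direct instrument and prior-outcome effects.
    """

    method = "POA-IV"
    augmented = True

    def _stage2_terms(self) -> list[str]:
        return ["const", "xhat", *self.covariates, "z", "y0"]

    def fit(self) -> EffectResults:
        s1 = self._stage1()
        diagnostics = {
            "first_stage_f_z": s1.wald("z"),
            "first_stage_f_y0z": s1.wald("y0:z"),
            "converged": True,
        }
        _warn_weak(diagnostics["first_stage_f_y0z"], "y0:z")
        work = self.frame.copy()
        work["xhat"] = s1.predict(build_design(work, s1.term_names))
        terms = self._stage2_terms()
        s2 = fit_glm(build_design(work, terms), work["y1"].to_numpy(float),
                     terms, self.second_stage)
        est, se = ame(s2, work, "xhat")
        return _results(self.method, est, se, len(work), self.level,
                        diagnostics, s2)


class PriorOutcomeCF(PriorOutcomeIV):
    """Prior-outcome-augmented control-function estimator."""

    method = "POA-CF"

    def fit(self) -> EffectResults:
        s1 = self._stage1()
        diagnostics = {
            "first_stage_f_z": s1.wald("z"),
            "first_stage_f_y0z": s1.wald("y0:z"),
            "converged": True,
        }
        _warn_weak(diagnostics["first_stage_f_y0z"], "y0:z")
        work = self.frame.copy()
        work["delta"] = work["x"].to_numpy(float) - s1.predict(
            build_design(work, s1.term_names))
        terms = ["const", "x", *self.covariates, "z", "y0", "delta", "delta:z"]
        s2 = fit_glm(build_design(work, terms), work["y1"].to_numpy(float),
                     terms, "logistic")
        est, se = ame(s2, work, "x")
        return _results(self.method, est, se, len(work), self.level,
                        diagnostics, s2)


# ---------------------------------------------------------------------------
# difference-in-difference
# ---------------------------------------------------------------------------

def stack_periods(data) -> pd.DataFrame:
    """Long (2n-row) period stack for difference-in-difference fitting.

    Each patient contributes one prior-period row (``p_star=0``, outcome
    ``y0``, confounder ``w0``) and one study-period row (``p_star=1``,
    outcome ``y1``, confounder ``w1``); the treatment indicator ``x_star``
    repeats across both rows.
    """
    frame = as_frame(data)
    for col in ("y0", "y1", "w0", "w1"):
        if col not in frame.columns:
            raise ValueError(f"cannot stack periods: column {col!r} missing")
    n = len(frame)
    stacked = pd.DataFrame({
        "patient_id": np.tile(frame["patient_id"].to_numpy(), 2),
        "y_star": np.concatenate([frame["y0"], frame["y1"]]).astype(float),
        "x_star": np.tile(frame["x"].to_numpy(float), 2),
        "p_star": np.repeat([0.0, 1.0], n),
        "w_star": np.concatenate([frame["w0"], frame["w1"]]).astype(float),
    })
    if "z" in frame.columns:
        stacked["z"] = np.tile(frame["z"].to_numpy(float), 2)
    return stacked


class DiD(EffectModel):
    """Difference-in-difference over the prior and study periods.

    A single regression on the stacked two-period data with period,
    treatment, their interaction, and period-specific confounder terms.  For
    the linear family the estimate is exactly the period-by-treatment
    interaction coefficient; for the (default) logistic family it is the
    difference-in-AME — the study-period treatment contrast of average
    predicted probabilities minus the prior-period contrast, evaluated at
    each patient's period-appropriate confounder value — with a delta-method
    SE on that four-way contrast.
    """

    method = "DiD"

    def __init__(self, data, include_z: bool = False, family: str = "logistic",
                 covariates: tuple = ("w_star",), level: float = 0.95):
        super().__init__(data, level)
        self.include_z = include_z
        self.family = family
        self.covariates = tuple(covariates)
        if include_z:
            self.method = "DiD+Z"

    def terms(self) -> list[str]:
        t = ["const", "p_star", "x_star", "p_star:x_star"]
        for c in self.covariates:
            t += [c, f"{c}:p_star"]
        if self.include_z:
            t += ["z", "z:p_star"]
        return t

    def fit(self) -> EffectResults:
        stacked = stack_periods(self.frame)
        for p in (0.0, 1.0):
            ys = stacked.loc[stacked["p_star"] == p, "y_star"]
            if ys.nunique() < 2:
                raise ValueError(
                    f"degenerate period p_star={int(p)}: all outcomes equal"
                )
        terms = self.terms()
        m = fit_glm(build_design(stacked, terms),
                    stacked["y_star"].to_numpy(float), terms, self.family)

        # four-way contrast at each patient's period-appropriate confounder
        frame = self.frame
        n = len(frame)
        designs = {}
        for p, xv in ((1, 1), (1, 0), (0, 1), (0, 0)):
            d = pd.DataFrame({
                "p_star": float(p),
                "x_star": float(xv),
                "w_star": frame["w1" if p == 1 else "w0"].to_numpy(float),
            })
            if self.include_z:
                d["z"] = frame["z"].to_numpy(float)
            designs[(p, xv)] = build_design(d, terms)

        X_hi = np.vstack([designs[(1, 1)], designs[(0, 0)]])
        X_lo = np.vstack([designs[(1, 0)], designs[(0, 1)]])
        # mean over the 2n stacked rows is half of the per-patient
        # [(p1,x1)-(p1,x0)] - [(p0,x1)-(p0,x0)] contrast
        est2, se2 = ame_contrast(m, X_hi, X_lo)
        est, se = 2.0 * est2, 2.0 * se2
        return _results(self.method, est, se, n, self.level,
                        {"converged": m.converged}, m)


# ---------------------------------------------------------------------------
# functional wrappers and method registry
# ---------------------------------------------------------------------------

def fit_cat(data, include_z: bool = False, include_y0: bool = False,
            **kw) -> EffectResults:
    return CaT(data, include_z=include_z, include_y0=include_y0, **kw).fit()


def fit_psm(data, include_y0: bool = False, caliper: float | None = None,
            **kw) -> EffectResults:
    return PSMatch(data, include_y0=include_y0, caliper=caliper, **kw).fit()


def fit_iv(data, include_y0: bool = False, **kw) -> EffectResults:
    return TwoStageIV(data, include_y0=include_y0, **kw).fit()


def fit_cf(data, include_y0: bool = False, **kw) -> EffectResults:
    return ControlFunction(data, include_y0=include_y0, **kw).fit()


def fit_did(data, include_z: bool = False, **kw) -> EffectResults:
    return DiD(data, include_z=include_z, **kw).fit()


def fit_poa_iv(data, **kw) -> EffectResults:
    return PriorOutcomeIV(data, **kw).fit()


def fit_poa_cf(data, **kw) -> EffectResults:
    return PriorOutcomeCF(data, **kw).fit()


#: Method-label registry used by the triangulation, study and CLI layers.
METHODS: dict[str, tuple[type[EffectModel], dict]] = {
    "cat": (CaT, {}),
    "cat_z": (CaT, {"include_z": True}),
    "psm": (PSMatch, {}),
    "iv": (TwoStageIV, {}),
    "cf": (ControlFunction, {}),
    "did": (DiD, {}),
    "did_z": (DiD, {"include_z": True}),
    "poa_iv": (PriorOutcomeIV, {}),
    "poa_cf": (PriorOutcomeCF, {}),
}


def make_estimator(label: str, data, **extra) -> EffectModel:
    """Instantiate an estimator from its registry label."""
    try:
        cls, kwargs = METHODS[label]
    except KeyError:
        raise ValueError(
            f"unknown method {label!r}; choose from {sorted(METHODS)}"
        ) from None
    merged = dict(kwargs)
    for k, v in extra.items():
        # only pass options the class constructor understands
        if k in cls.__init__.__code__.co_varnames:
            merged[k] = v
    return cls(data, **merged)


def fit_method(label: str, data, **extra) -> EffectResults:
    return make_estimator(label, data, **extra).fit()
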