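"""Scenario configurations for the two-period observational data generator.

A :class:`ScenarioConfig` bundles the data-generating coefficients with the
assumption-violation switches that define the named simulation scenarios:

* ``base1`` .. ``base8`` — the factorial crossing of unmeasured confounding
  (NUC violated), prior-outcome-driven treatment choice (DiD1 violated) and a
  direct instrument effect on the study outcome (exclusion/IV2 violated);
* ``poa1`` .. ``poa3`` — the prior-outcome-augmented IV scenarios, in which
  the provider preference additionally interacts with the prior outcome in
  the treatment model (``poa_relevance``).

The default coefficient values are calibrated, not transcribed: they are
chosen so that (i) event prevalence stays rare-ish (roughly 10–15%), (ii) the
provider-preference instrument is strong (first-stage F far above 10), and
(iii) the qualitative bias pattern of the estimator-by-scenario grid is
reproduced (difference-in-difference bias near -0.2 under DiD1 violation, IV
bias near +0.14 under exclusion violation, confounder-adjustment bias near
+0.03 under unmeasured confounding).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

# The six structural switches.  Each activates one set of arrows in the DGP.
FLAG_NAMES = (
    "nuc_violated",    # U -> X and U -> Y1 active
    "did1_violated",   # Y0 -> X active
    "iv2_violated",    # Z -> Y1 active (exclusion restriction broken)
    "y0_direct",       # Y0 -> Y1 active
    "y0_confounded",   # U -> Y0 active (DiD2-consistent confounding of Y0)
    "poa_relevance",   # Y0*Z -> X active (interaction instrument)
)

#: Default data-generating coefficients.  Outcome models are on the
#: probability scale (so the causal effect is an exact risk difference);
#: the treatment model is on the log-odds scale.
DEFAULT_COEF = {
    "z_prev": 0.5,    # cluster-level P(Z = 1)
    "w_rho": 0.5,     # corr(W0, W1); W1 = rho*W0 + sqrt(1-rho^2)*noise
    # prior-period outcome Y0 (probability scale)
    "y0_int": 0.12,
    "y0_w0": 0.02,
    "y0_u": 0.035,    # active iff y0_confounded
    # treatment X (log-odds scale)
    "x_int": -0.6,
    "x_z": 1.2,
    "x_w1": 0.4,
    "x_y0": 3.0,      # active iff did1_violated
    "x_u": 1.0,       # active iff nuc_violated
    "x_y0z": -3.0,    # active iff poa_relevance
    # study-period outcome Y1 (probability scale, additive treatment effect)
    "y1_int": 0.12,
    "y1_w1": 0.02,
    "y1_u": 0.035,    # active iff nuc_violated
    "y1_z": 0.04,     # active iff iv2_violated
    "y1_y0": 0.05,    # active iff y0_direct
}

_BASE_FLAGS = {
    "base1": (),
    "base2": ("did1_violated",),
    "base3": ("iv2_violated",),
    "base4": ("did1_violated", "iv2_violated"),
    "base5": ("nuc_violated", "y0_confounded"),
    "base6": ("nuc_violated", "did1_violated", "y0_confounded"),
    "base7": ("nuc_violated", "iv2_violated", "y0_confounded"),
    "base8": ("nuc_violated", "did1_violated", "iv2_violated", "y0_confounded"),
    # POA scenarios: all of NUC/DiD1/IV2 broken plus the interaction
    # instrument; the prior outcome is unconfounded in poa1/poa2 only.
    "poa1": ("nuc_violated", "did1_violated", "iv2_violated", "poa_relevance"),
    "poa2": ("nuc_violated", "did1_violated", "iv2_violated", "poa_relevance",
             "y0_direct"),
    "poa3": ("nuc_violated", "did1_violated", "iv2_violated", "poa_relevance",
             "y0_confounded"),
}

SCENARIO_IDS = tuple(_BASE_FLAGS) + ("custom",)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one simulated study design."""

    scenario_id: str = "custom"
    n: int = 5000
    n_g: int = 50
    beta: float = 0.1            # true causal risk difference in the study period
    coef: dict = field(default_factory=lambda: dict(DEFAULT_COEF))
    nuc_violated: bool = False
    did1_violated: bool = False
    iv2_violated: bool = False
    y0_direct: bool = False
    y0_confounded: bool = False
    poa_relevance: bool = False
    prob_floor: float = 0.01     # epsilon: probabilities clamped into [eps, 1-eps]
    clamp_tol: float = 0.01      # max tolerated fraction of clamped patients

    def __post_init__(self):
        if self.n_g < 2:
            raise ValueError("n_g must be at least 2")
        if self.n % self.n_g != 0:
            raise ValueError(f"n={self.n} not divisible by n_g={self.n_g}")
        if not -1.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [-1, 1]")
        if not 0.0 < self.prob_floor < 0.5:
            raise ValueError("prob_floor must lie in (0, 0.5)")
        unknown = set(self.coef) - set(DEFAULT_COEF)
        if unknown:
            raise ValueError(f"unknown coefficient names: {sorted(unknown)}")

    @property
    def flags(self) -> dict[str, bool]:
        return {name: getattr(self, name) for name in FLAG_NAMES}

    @property
    def cluster_size(self) -> int:
        return self.n // self.n_g

    def with_overrides(self, **overrides) -> "ScenarioConfig":
        """Return a copy with field/coefficient overrides applied."""
        coef_over = {k: v for k, v in overrides.items() if k in DEFAULT_COEF}
        field_over = {k: v for k, v in overrides.items() if k not in coef_over}
        known = {"n", "n_g", "beta", "prob_floor", "clamp_tol", "scenario_id",
                 *FLAG_NAMES}
        bad = set(field_over) - known
        if bad:
            raise ValueError(f"unknown override fields: {sorted(bad)}")
        coef = dict(self.coef)
        coef.update(coef_over)
        return replace(self, coef=coef, **field_over)

    def to_dict(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "n": self.n,
            "n_g": self.n_g,
            "beta": self.beta,
            "prob_floor": self.prob_floor,
            "clamp_tol": self.clamp_tol,
            "coef": dict(self.coef),
            "flags": self.flags,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        flags = d.pop("flags", {})
        bad = set(flags) - set(FLAG_NAMES)
        if bad:
            raise ValueError(f"unknown flags: {sorted(bad)}")
        coef = dict(DEFAULT_COEF)
        coef.update(d.pop("coef", {}))
        known = {"scenario_id", "n", "n_g", "beta", "prob_floor", "clamp_tol"}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(coef=coef, **d, **{k: bool(v) for k, v in flags.items()})


def make_scenario_config(scenario_id: str, overrides: dict | None = None) -> ScenarioConfig:
    """Build the configuration for a named scenario (or ``"custom"``).

    For named scenarios the violation-flag pattern is fixed; an override that
    contradicts it is rejected (use ``"custom"`` for free-form designs).
    """
    overrides = dict(overrides or {})
    if scenario_id not in SCENARIO_IDS:
        raise ValueError(
            f"unknown scenario_id {scenario_id!r}; choose one of {SCENARIO_IDS}"
        )
    if scenario_id == "custom":
        flag_over = {k: bool(overrides.pop(k)) for k in list(overrides)
                     if k in FLAG_NAMES}
        cfg = ScenarioConfig(scenario_id="custom", **flag_over)
        return cfg.with_overrides(**overrides)

    flags = {name: name in _BASE_FLAGS[scenario_id] for name in FLAG_NAMES}
    for name in FLAG_NAMES:
        if name in overrides:
            if bool(overrides[name]) != flags[name]:
                raise ValueError(
                    f"override {name}={overrides[name]} contradicts scenario "
                    f"{scenario_id!r}; use scenario_id='custom' instead"
                )
            overrides.pop(name)
    cfg = ScenarioConfig(scenario_id=scenario_id, **flags)
    return cfg.with_overrides(**overrides)
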