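"""Estimators: closed-form equivalences, AME behaviour, matching, warnings."""

import numpy as np
import pandas as pd
import pytest

import tricause as tc
from tricause import (CaT, ControlFunction, DiD, PSMatch, PriorOutcomeIV,
                      TwoStageIV, WeakInstrumentWarning)
from tricause.estimators import ame, as_frame, build_design, stack_periods
from tricause.glm import fit_glm


def frame_from(n, seed=0, **cols):
    rng = np.random.default_rng(seed)
    base = {
        "patient_id": np.arange(n),
        "cluster_id": np.zeros(n, dtype=int),
        "z": np.zeros(n, dtype=int),
        "x": rng.integers(0, 2, n),
        "y0": rng.integers(0, 2, n),
        "y1": rng.integers(0, 2, n),
        "w0": rng.standard_normal(n),
        "w1": rng.standard_normal(n),
    }
    base.update(cols)
    return pd.DataFrame(base)


# ---------------------------------------------------------------------------
# AME
# ---------------------------------------------------------------------------

def test_ame_zero_coefficient_gives_zero(noise_frame):
    terms = ["const", "x", "w1"]
    m = fit_glm(build_design(noise_frame, terms),
                noise_frame["y1"].to_numpy(float), terms)
    m.params[terms.index("x")] = 0.0
    est, _ = ame(m, noise_frame, "x")
    assert est == 0.0


def test_ame_saturated_logistic_equals_proportion_difference(noise_frame):
    """Logistic y1 ~ x alone: AME must equal the raw 2x2 rate difference."""
    res = CaT(noise_frame, covariates=()).fit()
    g = noise_frame.groupby("x")["y1"].mean()
    assert res.beta_hat == pytest.approx(g.loc[1] - g.loc[0], abs=1e-9)


def test_ame_linear_family_equals_coefficient(noise_frame):
    res = CaT(noise_frame, family="linear").fit()
    assert res.beta_hat == pytest.approx(res.model.coef["x"], abs=1e-12)
    assert res.se == pytest.approx(np.sqrt(
        res.model.cov[res.model.term_names.index("x")][
            res.model.term_names.index("x")]), rel=1e-9)


def test_ame_rejects_non_binary_target(noise_frame):
    terms = ["const", "x", "w1"]
    m = fit_glm(build_design(noise_frame, terms),
                noise_frame["y1"].to_numpy(float), terms)
    with pytest.raises(ValueError, match="not binary"):
        ame(m, noise_frame, "w1")
    with pytest.raises(ValueError, match="not a term"):
        ame(m, noise_frame, "y0")


# ---------------------------------------------------------------------------
# IV: Wald-ratio reduction
# ---------------------------------------------------------------------------

def _wald_ratio_fixture():
    """Group means E[Y1|Z=1]=0.6, E[Y1|Z=0]=0.4, E[X|Z=1]=0.8, E[X|Z=0]=0.3."""
    def block(z, n, px, py):
        return pd.DataFrame({
            "patient_id": 0, "cluster_id": z, "z": z,
            "x": [1] * int(n * px) + [0] * (n - int(n * px)),
            "y1": [1] * int(n * py) + [0] * (n - int(n * py)),
            "y0": 0, "w0": 0.0, "w1": 0.0,
        })
    df = pd.concat([block(1, 10, 0.8, 0.6), block(0, 10, 0.3, 0.4)],
                   ignore_index=True)
    df["patient_id"] = np.arange(len(df))
    return df


def test_iv_reduces_to_wald_ratio_without_covariates():
    df = _wald_ratio_fixture()
    with pytest.warns(WeakInstrumentWarning):
        res = TwoStageIV(df, second_stage="linear", covariates=()).fit()
    assert res.beta_hat == pytest.approx((0.6 - 0.4) / (0.8 - 0.3), abs=1e-9)


def test_first_stage_f_strong_and_null(base1_data):
    assert tc.first_stage_f(base1_data, "z") > 10
    # irrelevant instrument: F has mean ~1 under the null
    cfg = tc.make_scenario_config("custom", {"x_z": 0.0, "n": 2000, "n_g": 20})
    fs = [tc.first_stage_f(tc.simulate_dataset(cfg, s), "z")
          for s in range(20)]
    assert np.mean(fs) < 4.0


def test_interaction_instrument_f(poa1_data):
    assert tc.first_stage_f(poa1_data, "y0z") > 10
    cfg = tc.make_scenario_config("custom", {
        "nuc_violated": True, "did1_violated": True, "iv2_violated": True,
        "poa_relevance": True, "x_y0z": 0.0})
    null_data = tc.simulate_dataset(cfg, 1)
    assert tc.first_stage_f(null_data, "y0z") < 10


def test_weak_interaction_instrument_warns_and_inflates_se(poa1_data):
    cfg = tc.make_scenario_config("custom", {
        "nuc_violated": True, "did1_violated": True, "iv2_violated": True,
        "poa_relevance": True, "x_y0z": 0.0})
    weak = tc.simulate_dataset(cfg, 1)
    with pytest.warns(WeakInstrumentWarning):
        res_weak = PriorOutcomeIV(weak).fit()
    res_strong = PriorOutcomeIV(poa1_data).fit()
    assert res_weak.se > 2 * res_strong.se


def test_cf_residual_carries_no_signal_without_confounding():
    """Unconfounded data, strong instrument: CF tracks the plain regression."""
    cfg = tc.make_scenario_config("base1", {"n": 50_000, "n_g": 500})
    d = tc.simulate_dataset(cfg, 21)
    res_cf = ControlFunction(d).fit()
    res_cat = CaT(d).fit()
    j = res_cf.model.term_names.index("delta")
    delta_se = np.sqrt(res_cf.model.cov[j, j])
    assert abs(res_cf.model.params[j]) < 3 * delta_se
    assert res_cf.beta_hat == pytest.approx(
        res_cat.beta_hat, abs=3 * np.hypot(res_cf.se, res_cat.se))


# ---------------------------------------------------------------------------
# period stacking and DiD
# ---------------------------------------------------------------------------

def test_stack_periods_definition_single_patient():
    df = frame_from(1, x=[1], y0=[0], y1=[1], w0=[0.3], w1=[0.7])
    s = stack_periods(df)
    assert len(s) == 2
    prior = s[s.p_star == 0].iloc[0]
    study = s[s.p_star == 1].iloc[0]
    assert (prior.y_star, prior.x_star, prior.w_star) == (0.0, 1.0, 0.3)
    assert (study.y_star, study.x_star, study.w_star) == (1.0, 1.0, 0.7)


def test_stack_periods_tabulation_oracle(noise_frame):
    s = stack_periods(noise_frame)
    assert len(s) == 2 * len(noise_frame)
    assert (s.groupby("patient_id").size() == 2).all()
    means = s.groupby(["p_star", "x_star"])["y_star"].mean()
    direct = {
        (0.0, xv): noise_frame.loc[noise_frame.x == xv, "y0"].mean()
        for xv in (0, 1)
    } | {
        (1.0, xv): noise_frame.loc[noise_frame.x == xv, "y1"].mean()
        for xv in (0, 1)
    }
    for key, val in direct.items():
        assert means.loc[key] == pytest.approx(val, abs=1e-12)


def test_did_linear_equals_four_mean_oracle(noise_frame):
    res = DiD(noise_frame, family="linear", covariates=()).fit()
    g = noise_frame.groupby("x")[["y0", "y1"]].mean()
    oracle = (g.loc[1, "y1"] - g.loc[0, "y1"]) - (g.loc[1, "y0"] - g.loc[0, "y0"])
    assert res.beta_hat == pytest.approx(oracle, abs=1e-9)


def test_did_parallel_gaps_cancel():
    """Identical arm-wise event-rate gaps in both periods give a null DiD."""
    n = 200
    x = np.repeat([1, 0], n // 2)
    y = np.tile([1] * 30 + [0] * 70, 2)[:n]  # same pattern in both arms? no:
    # build explicitly: treated rate .4, control rate .2 in BOTH periods
    y0 = np.concatenate([[1] * 40 + [0] * 60, [1] * 20 + [0] * 80])
    df = frame_from(n, x=x, y0=y0, y1=y0.copy())
    res = DiD(df, family="linear", covariates=()).fit()
    assert res.beta_hat == pytest.approx(0.0, abs=1e-9)


def test_did_degenerate_period_errors():
    df = frame_from(100)
    df["y0"] = 0
    with pytest.raises(ValueError, match="degenerate"):
        DiD(df).fit()


# ---------------------------------------------------------------------------
# propensity matching
# ---------------------------------------------------------------------------

def test_psm_constant_score_matches_everyone():
    n = 40
    df = frame_from(n, w1=np.zeros(n), x=np.repeat([1, 0], n // 2))
    res = PSMatch(df).fit()
    assert res.diagnostics["n_pairs"] == n // 2
    g = df.groupby("x")["y1"].mean()
    assert res.beta_hat == pytest.approx(g.loc[1] - g.loc[0], abs=1e-8)


def test_psm_pairs_match_exhaustive_search():
    """n=8 hand-laid scores: greedy pairing equals brute-force best match."""
    df = frame_from(8, x=[1, 1, 1, 1, 0, 0, 0, 0],
                    w1=[0.0, 1.0, 2.0, 5.0, 0.1, 1.1, 2.1, 9.0])
    model = PSMatch(df)
    terms = model.propensity_terms()
    ps = fit_glm(build_design(as_frame(df), terms),
                 df["x"].to_numpy(float), terms).predict(
        build_design(as_frame(df), terms))
    # expected: each treated patient's nearest free control in score space
    res = model.fit()
    assert res.diagnostics["n_pairs"] == 4
    assert res.diagnostics["matched_fraction"] == 1.0
    # monotone scores => treated i matches control with the closest w1
    assert abs(res.diagnostics["smd_post_w1"]) <= abs(
        res.diagnostics["smd_pre_w1"]) + 1e-12
    assert ps.shape == (8,)


def test_psm_agrees_with_cat_when_unconfounded(base1_data):
    res_psm = PSMatch(base1_data, seed=3).fit()
    res_cat = CaT(base1_data).fit()
    assert res_psm.beta_hat == pytest.approx(
        res_cat.beta_hat, abs=3 * np.hypot(res_psm.se, res_cat.se))


def test_psm_requires_two_per_arm():
    df = frame_from(10, x=[1] + [0] * 9)
    with pytest.raises(ValueError, match="arm"):
        PSMatch(df).fit()


# ---------------------------------------------------------------------------
# result invariants and firewalling
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("label", sorted(tc.METHODS))
def test_result_invariants_all_methods(base1_data, label):
    res = tc.fit_method(label, base1_data)
    assert res.ci_low <= res.beta_hat <= res.ci_high
    assert res.se > 0
    assert 0.0 <= res.p_value <= 1.0
    assert -1.0 <= res.beta_hat <= 1.0
    assert res.n_used > 0


@pytest.mark.parametrize("label", ["cat", "iv", "cf", "did", "poa_iv", "poa_cf"])
def test_oracle_columns_never_used(base1_data, label):
    public = base1_data.public()
    assert tc.fit_method(label, base1_data).beta_hat == pytest.approx(
        tc.fit_method(label, public).beta_hat, abs=1e-12)


def test_separation_error_names_term():
    df = frame_from(100)
    df["y1"] = df["x"]
    with pytest.raises(Exception, match="separation"):
        CaT(df).fit()
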