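"""Study orchestration: performance metrics, determinism, preference IV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import tricause as tc
from tricause import (build_preference_iv, performance_metrics,
                      run_qtest_study, run_simulation_study)


# ---------------------------------------------------------------------------
# performance metrics
# ---------------------------------------------------------------------------

def test_metrics_perfect_estimates():
    cell = performance_metrics([0.1] * 5, [0.01] * 5,
                               [(0.05, 0.15)] * 5, [0.001] * 5, truth=0.1)
    assert cell["bias"][0] == 0.0
    assert cell["mse"][0] == 0.0
    assert cell["coverage"][0] == 1.0


def test_metrics_hand_arithmetic():
    cell = performance_metrics([0.0, 0.2], [0.1, 0.1],
                               [(-0.1, 0.1), (0.1, 0.3)], [0.5, 0.01],
                               truth=0.1)
    assert cell["bias"][0] == pytest.approx(0.0)
    assert cell["emp_se"][0] == pytest.approx(np.std([0.0, 0.2], ddof=1))
    assert cell["mse"][0] == pytest.approx(0.01)
    assert cell["coverage"][0] == 1.0
    assert cell["t1e"][0] == 0.5


def test_coverage_mcse_closed_form():
    rng = np.random.default_rng(0)
    R = 1000
    est = rng.normal(0.1, 0.01, R)
    covered = int(0.95 * R)
    cis = [(0.0, 1.0)] * covered + [(0.5, 0.6)] * (R - covered)
    cell = performance_metrics(est, np.full(R, 0.01), cis, np.full(R, 0.5),
                               truth=0.1)
    assert cell["coverage"][0] == pytest.approx(0.95)
    assert cell["coverage"][1] == pytest.approx(
        np.sqrt(0.95 * 0.05 / R), rel=1e-9)  # ~0.0069 at R=1000


@given(st.lists(st.floats(-0.5, 0.5), min_size=3, max_size=40),
       st.floats(-0.2, 0.2))
@settings(deadline=None, max_examples=50, derandomize=True)
def test_mse_decomposition_property(estimates, truth):
    """mse = bias^2 + empSE^2 * (R-1)/R for any estimate vector."""
    R = len(estimates)
    cell = performance_metrics(estimates, [0.1] * R, [(0, 0)] * R, [1.0] * R,
                               truth)
    bias, emp_se, mse = (cell[k][0] for k in ("bias", "emp_se", "mse"))
    assert mse == pytest.approx(bias**2 + emp_se**2 * (R - 1) / R,
                                abs=1e-12, rel=1e-9)


def test_metrics_validation():
    with pytest.raises(ValueError):
        performance_metrics([0.1], [0.1], [(0, 1)], [0.5], 0.1)
    with pytest.raises(ValueError):
        performance_metrics([0.1, 0.2], [0.1], [(0, 1)] * 2, [0.5] * 2, 0.1)


# ---------------------------------------------------------------------------
# simulation study
# ---------------------------------------------------------------------------

def test_study_reproducible_and_mcse_scaling():
    cfg = tc.make_scenario_config("base1", {"n": 500, "n_g": 10})
    a = run_simulation_study(cfg, ["cat"], n_reps=8, master_seed=3)
    b = run_simulation_study(cfg, ["cat"], n_reps=8, master_seed=3)
    pd.testing.assert_frame_equal(a.table, b.table)
    big = run_simulation_study(cfg, ["cat"], n_reps=32, master_seed=3)
    # bias MCSE shrinks like 1/sqrt(R) (up to sampling noise in empSE)
    assert big.cell("base1", "cat")["bias"][1] < a.cell("base1", "cat")["bias"][1]


def test_study_auto_adjustment_includes_z_when_exclusion_fails():
    kw = tc.scenario_method_kwargs(tc.make_scenario_config("base3", {}))
    assert kw["cat"] == {"include_z": True}
    assert kw["did"] == {"include_z": True}
    kw_poa2 = tc.scenario_method_kwargs(tc.make_scenario_config("poa2", {}))
    assert kw_poa2["cat"]["include_y0"]
    assert tc.scenario_method_kwargs(
        tc.make_scenario_config("base3", {}), strict=True) == {}


def test_study_null_truth_resimulates_at_zero():
    cfg = tc.make_scenario_config("base1", {"n": 500, "n_g": 10})
    s = run_simulation_study(cfg, ["cat"], n_reps=10, master_seed=1,
                             null_truth=True)
    assert abs(s.value("base1", "cat", "bias")) < 0.05


def test_qtest_study_degenerate_alpha():
    cfg = tc.make_scenario_config("base1", {"n": 400, "n_g": 10})
    tab = run_qtest_study(cfg, [("cat", "did")], n_reps=50, B=100,
                          master_seed=2, alpha=1.0)
    assert tab["rejection_rate"].iloc[0] == 1.0


def test_qtest_study_validation():
    cfg = tc.make_scenario_config("base1", {})
    with pytest.raises(ValueError):
        run_qtest_study(cfg, [("cat", "did")], n_reps=10, B=200)
    with pytest.raises(ValueError):
        run_qtest_study(cfg, [("cat", "did")], n_reps=100, B=10)


# ---------------------------------------------------------------------------
# preference instrument
# ---------------------------------------------------------------------------

def records(provider, treatments, start_pid=0):
    return pd.DataFrame({
        "provider_id": provider,
        "patient_id": np.arange(start_pid, start_pid + len(treatments)),
        "order_index": np.arange(1, len(treatments) + 1),
        "treatment": treatments,
    })


def test_preference_iv_hand_laid_sequence():
    z = build_preference_iv(records("a", [1, 0, 0, 1]))
    # patient 0 (first treated) excluded; others inherit previous choice
    assert list(z.index) == [1, 2, 3]
    assert list(z.values) == [1, 0, 0]


def test_preference_iv_single_patient_provider():
    z = build_preference_iv(records("solo", [1]))
    assert len(z) == 0


def test_preference_iv_duplicate_order_errors():
    r = records("a", [1, 0, 1])
    r.loc[2, "order_index"] = 2
    with pytest.raises(ValueError, match="duplicate"):
        build_preference_iv(r)


def test_preference_iv_window_majority():
    z = build_preference_iv(records("a", [1, 1, 0, 0, 0]), window=3)
    # patient 3 sees [1,1,0] -> 1; patient 4 sees [1,0,0] -> 0
    assert z.loc[3] == 1 and z.loc[4] == 0


def test_sticky_preference_stream_yields_strong_instrument():
    """Providers with sticky preferences: constructed Z passes F > 10."""
    rng = np.random.default_rng(8)
    n_prov, per = 40, 50
    frames = []
    pid = 0
    for p in range(n_prov):
        pref = rng.random() < 0.5
        tx = np.where(rng.random(per) < 0.85, int(pref), 1 - int(pref))
        frames.append(records(f"p{p}", tx, start_pid=pid))
        pid += per
    recs = pd.concat(frames, ignore_index=True)
    z = build_preference_iv(recs)
    merged = recs.set_index("patient_id").join(z.rename("z_iv"), how="inner")
    df = pd.DataFrame({
        "patient_id": merged.index,
        "cluster_id": pd.factorize(merged["provider_id"])[0],
        "z": merged["z_iv"].to_numpy(),
        "x": merged["treatment"].to_numpy(int),
        "y0": 0, "y1": 0,
        "w0": rng.standard_normal(len(merged)),
        "w1": rng.standard_normal(len(merged)),
    })
    assert tc.first_stage_f(df, "z") > 10
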