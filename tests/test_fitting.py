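"""Tests of the standard (3-parameter + Look-Locker) and simulation-based
T1 estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mollimap.bloch import TissueParams
from mollimap.fitting import (
    fit_simulation,
    fit_standard,
    fit_t1_map,
    generate_deviation_curves,
)
from mollimap.sequences import MOLLIProtocol, RecoveryCurve, simulate_molli

from oracles import grid_search_three_param

DEFAULT_TIS = np.array([100, 1100, 2100, 180, 1180, 2180, 260, 1260, 2260, 3260, 4260.0])


def _exact_curve(a, b, t1_star, ti=DEFAULT_TIS):
    return RecoveryCurve(ti, a - b * np.exp(-ti / t1_star))


@pytest.mark.parametrize(
    "a, b, t1_star, expected_t1",
    [
        (1.0, 2.0, 800.0, 800.0),     # ideal IR: Look-Locker correction is identity
        (1.0, 1.8, 1000.0, 800.0),    # closed-form correction T1 = T1*(B/A - 1)
    ],
)
def test_standard_fit_exact_data(a, b, t1_star, expected_t1):
    res = fit_standard(_exact_curve(a, b, t1_star))
    assert res.converged
    assert res.t1 == pytest.approx(expected_t1, rel=1e-6)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.floats(0.3, 3.0),
    st.floats(1.2, 2.2),
    st.floats(300, 2500),
)
def test_standard_fit_recovers_parameters_exactly(a, ratio, t1_star):
    """On data exactly satisfying the exponential model the fit recovers
    (A, B, T1*) to 1e-6 relative."""
    b = a * ratio
    res = fit_standard(_exact_curve(a, b, t1_star))
    assert res.converged
    assert res.params.a == pytest.approx(a, rel=1e-6)
    assert res.params.b == pytest.approx(b, rel=1e-6)
    assert res.params.t1_star == pytest.approx(t1_star, rel=1e-6)


def test_standard_fit_polarity_restoration_on_magnitude_data():
    curve = _exact_curve(1.0, 2.0, 900.0)
    signed = fit_standard(curve)
    mag = fit_standard(curve.to_magnitude())
    assert mag.converged
    assert mag.t1 == pytest.approx(signed.t1, rel=1e-6)
    assert mag.params.polarity_index == int(np.sum(curve.sorted().signal < 0))


def test_standard_fit_flags_degenerate_input():
    ti = DEFAULT_TIS
    res = fit_standard(RecoveryCurve(ti, np.linspace(-1, 1, ti.size)[::-1]))
    assert not res.converged
    with pytest.raises(ValueError):
        fit_standard(RecoveryCurve([100.0, 200, 300], [0.1, 0.2, 0.3]))


def test_standard_fit_on_simulated_molli_matches_grid_oracle(protocol):
    """On a noiseless simulated curve the LM fit agrees with a dense-grid
    least-squares oracle and sits below the true T1 (readout bias)."""
    curve = simulate_molli(TissueParams(1180.0, 60.0), protocol, eta=1.0, alpha_actual=35.0)
    res = fit_standard(curve)
    a, b, t1s = grid_search_three_param(curve.ti, curve.signal, np.arange(400.0, 2000.0, 1.0))
    t1_oracle = t1s * (b / a - 1.0)
    assert res.t1 == pytest.approx(t1_oracle, rel=0.005)
    assert res.t1 < 1180.0


def test_simulation_fit_self_consistency(protocol):
    """Noiseless inverse crime: the fit recovers the generating T1."""
    curve = simulate_molli(TissueParams(1180.0, 45.0), protocol, eta=0.92, alpha_actual=30.0)
    res = fit_simulation(curve, t2=45.0, eta=0.92, alpha_actual=30.0, protocol=protocol)
    assert res.converged
    assert res.t1 == pytest.approx(1180.0, rel=1e-3)


def test_simulation_fit_self_consistency_random_draws(rng, protocol):
    """Exact self-recovery (< 0.1%) across 20 random parameter draws."""
    for _ in range(20):
        t1 = rng.uniform(400, 2400)
        t2 = rng.uniform(30, 90)
        eta = rng.uniform(0.85, 1.0)
        alpha = rng.uniform(15, 45)
        curve = simulate_molli(TissueParams(t1, t2), protocol, eta=eta, alpha_actual=alpha)
        res = fit_simulation(curve, t2=t2, eta=eta, alpha_actual=alpha, protocol=protocol)
        assert res.converged
        assert abs(res.t1 - t1) / t1 < 1e-3


def test_simulation_fit_matches_fine_grid_search(protocol):
    """Nelder-Mead lands on the global optimum found by a 0.1 ms grid."""
    curve = simulate_molli(TissueParams(1300.0, 45.0), protocol, eta=0.92, alpha_actual=35.0)
    res = fit_simulation(curve, t2=48.1, eta=0.92, alpha_actual=35.0, protocol=protocol)

    def rss(t1):
        sim = simulate_molli(TissueParams(t1, 48.1), protocol, eta=0.92, alpha_actual=35.0)
        m, d = sim.signal, curve.signal
        s = np.dot(m, d) / np.dot(m, m)
        return float(np.sum((d - s * m) ** 2))

    coarse = np.arange(1100.0, 1500.0, 10.0)
    t1c = coarse[np.argmin([rss(t) for t in coarse])]
    fine = np.arange(t1c - 15.0, t1c + 15.0, 0.1)
    t1_grid = fine[np.argmin([rss(t) for t in fine])]
    assert abs(res.t1 - t1_grid) < 0.5


def test_simulation_fit_t2_bias_sensitivity(protocol):
    """Supplying a +3.1 ms overestimated T2 biases the fitted T1 downward
    by well under 1% at T1 = 1300 ms."""
    curve = simulate_molli(TissueParams(1300.0, 45.0), protocol, eta=0.92, alpha_actual=35.0)
    res = fit_simulation(curve, t2=48.1, eta=0.92, alpha_actual=35.0, protocol=protocol)
    assert res.converged
    assert res.t1 < 1300.0
    assert abs(res.t1 - 1300.0) / 1300.0 < 0.01


def test_simulation_fit_error_is_continuous_in_supplied_t2_and_alpha(protocol):
    """No branch jumps: the T1 error varies smoothly across +/-10%
    perturbations of the fixed parameters."""
    curve = simulate_molli(TissueParams(1180.0, 45.0), protocol, eta=0.92, alpha_actual=30.0)
    errs_t2 = []
    for t2 in np.linspace(40.5, 49.5, 7):
        res = fit_simulation(curve, t2=t2, eta=0.92, alpha_actual=30.0, protocol=protocol)
        errs_t2.append(res.t1 - 1180.0)
    errs_a = []
    for alpha in np.linspace(27.0, 33.0, 7):
        res = fit_simulation(curve, t2=45.0, eta=0.92, alpha_actual=alpha, protocol=protocol)
        errs_a.append(res.t1 - 1180.0)
    assert np.max(np.abs(np.diff(errs_t2))) < 0.02 * 1180.0
    assert np.max(np.abs(np.diff(errs_a))) < 0.02 * 1180.0


def test_simulation_fit_validates_inputs(protocol):
    curve = _exact_curve(1.0, 2.0, 800.0)
    with pytest.raises(ValueError):
        fit_simulation(curve, t2=-1.0, eta=0.92, alpha_actual=35.0, protocol=protocol)
    with pytest.raises(ValueError):
        fit_simulation(curve, t2=45.0, eta=1.5, alpha_actual=35.0, protocol=protocol)
    with pytest.raises(ValueError):
        fit_simulation(curve, t2=45.0, eta=0.92, alpha_actual=0.0, protocol=protocol)


def test_deviation_sweep_dataset_ranges():
    df = generate_deviation_curves(1, n_points=5)
    assert df["varied"].unique().tolist() == ["t1"]
    assert df["value"].min() == 400.0 and df["value"].max() == 2400.0
    df4 = generate_deviation_curves(4, n_points=4)
    assert df4["value"].min() == 0.85 and df4["value"].max() == 1.0


def test_deviation_vanishes_at_small_flip_angle(protocol):
    """With a near-zero readout flip angle and perfect inversion the
    standard fit is nearly unbiased."""
    df = generate_deviation_curves(
        {"varied": "alpha", "range": (0.5, 0.5), "t1": 1180.0, "t2": 60.0, "alpha": None, "eta": 1.0},
        n_points=1,
    )
    assert abs(df["rel_deviation"].iloc[0]) < 0.02


def test_deviation_magnitude_grows_with_flip_angle():
    df = generate_deviation_curves(3, n_points=8)  # alpha sweep 5-75 deg
    dev = -df["rel_deviation"].to_numpy()  # underestimation is negative
    assert np.all(dev > 0)
    assert np.all(np.diff(dev) > 0)


def test_imperfect_inversion_worsens_underestimation(protocol):
    curve_eta1 = simulate_molli(TissueParams(1180, 60), protocol, eta=1.0, alpha_actual=35.0)
    curve_eta09 = simulate_molli(TissueParams(1180, 60), protocol, eta=0.9, alpha_actual=35.0)
    dev1 = fit_standard(curve_eta1).t1 - 1180.0
    dev09 = fit_standard(curve_eta09).t1 - 1180.0
    assert dev09 < dev1 < 0


def test_fit_t1_map_standard_and_simulation_agree_with_truth(protocol):
    ti = protocol.inversion_times()
    t1s = np.array([[600.0, 1200.0], [1800.0, 2400.0]])
    stack = np.stack(
        [
            simulate_molli(TissueParams(t1, 45.0), protocol, eta=0.92, alpha_actual=35.0).signal
            for t1 in t1s.ravel()
        ]
    ).reshape(2, 2, -1)
    t1_map, ok = fit_t1_map(stack, ti, "fit-sim", protocol, t2=45.0, eta=0.92, alpha=35.0)
    assert ok.all()
    np.testing.assert_allclose(t1_map, t1s, rtol=2e-3)
    t1_std, ok_std = fit_t1_map(stack, ti, "standard", protocol)
    assert ok_std.all()
    assert np.all(t1_std < t1s)  # systematic underestimation
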