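"""Unit and property tests for the elementary Bloch operators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mollimap.bloch import (
    BlochOperator,
    MagnetizationState,
    TissueParams,
    compose,
    identity,
    precess,
    precession,
    relax,
    relaxation,
    rotate,
    rotation,
)

SETTINGS = dict(max_examples=50, deadline=None, derandomize=True)


@pytest.mark.parametrize(
    "alpha, start, expected",
    [
        (90.0, (0, 0, 1), (0, 1, 0)),
        (180.0, (0, 0, 1), (0, 0, -1)),
        (35.0, (0, 0, 1), (0, math.sin(math.radians(35)), math.cos(math.radians(35)))),
        (0.0, (0.3, -0.2, 0.9), (0.3, -0.2, 0.9)),
    ],
)
def test_rotation_examples(alpha, start, expected):
    out = rotate(alpha, MagnetizationState(*start))
    np.testing.assert_allclose(out.as_array(), expected, atol=1e-12)


@settings(**SETTINGS)
@given(st.floats(-720, 720))
def test_rotation_is_orthogonal_and_norm_preserving(alpha):
    R = rotation(alpha).matrix
    np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-12)
    m = MagnetizationState(0.1, -0.5, 0.7)
    assert rotate(alpha, m).norm == pytest.approx(m.norm, abs=1e-12)


def test_rotation_rejects_non_finite():
    with pytest.raises(ValueError):
        rotation(math.nan)


def test_precession_identity_and_quarter_period():
    m = MagnetizationState(0.4, 0.1, 0.6)
    out = precess(17.0, 0.0, m)
    np.testing.assert_allclose(out.as_array(), m.as_array(), atol=1e-12)
    # 100 Hz for 2.5 ms is a quarter turn; the printed matrix convention
    # sends +x to -y.
    out = precess(2.5, 100.0, MagnetizationState(1, 0, 0))
    np.testing.assert_allclose(out.as_array(), (0, -1, 0), atol=1e-12)


@settings(**SETTINGS)
@given(st.floats(0, 50), st.floats(0, 50), st.floats(-500, 500))
def test_precession_group_property(t_a, t_b, df):
    split = precession(t_a, df).then(precession(t_b, df))
    joint = precession(t_a + t_b, df)
    np.testing.assert_allclose(split.matrix, joint.matrix, atol=1e-9)


def test_precession_rejects_negative_time():
    with pytest.raises(ValueError):
        precession(-1.0, 100.0)


def test_relaxation_closed_forms():
    tissue = TissueParams(t1=1000.0, t2=60.0)
    # Long time: equilibrium regardless of start.
    out = relax(100 * tissue.t1, tissue, MagnetizationState(0.5, -0.5, -1.0))
    np.testing.assert_allclose(out.as_array(), (0, 0, 1), atol=1e-12)
    # One T1 from a saturated state.
    out = relax(tissue.t1, tissue, MagnetizationState(0, 0, 0))
    assert out.mz == pytest.approx(1 - math.exp(-1), abs=1e-12)
    # One T2 decays the transverse part by e^-1.
    out = relax(tissue.t2, tissue, MagnetizationState(1, 0, 1))
    assert out.mx == pytest.approx(math.exp(-1), abs=1e-12)
    assert out.mz == pytest.approx(1 - (1 - 1) * math.exp(-tissue.t2 / tissue.t1), abs=1e-12)


def test_relaxation_contracts_toward_equilibrium():
    tissue = TissueParams(t1=800.0, t2=50.0)
    eq = np.array([0.0, 0.0, tissue.m0])
    m = MagnetizationState(0.7, -0.2, -0.6)
    dist = [np.linalg.norm(relax(t, tissue, m).as_array() - eq) for t in np.linspace(0, 3000, 40)]
    assert all(b <= a + 1e-12 for a, b in zip(dist, dist[1:]))


def test_relaxation_rejects_negative_time():
    with pytest.raises(ValueError):
        relaxation(-0.1, TissueParams(1000, 50))


def test_tissue_validation():
    with pytest.raises(ValueError):
        TissueParams(t1=-5, t2=50)
    with pytest.raises(ValueError):
        TissueParams(t1=1000, t2=0)
    with pytest.warns(UserWarning):
        TissueParams(t1=100, t2=200)


def test_compose_empty_is_identity():
    op = compose([])
    m = MagnetizationState(0.2, 0.3, 0.4)
    np.testing.assert_allclose(op(m).as_array(), m.as_array(), atol=1e-15)


def test_compose_inverse_rotations_cancel():
    op = compose([rotation(37.0), rotation(-37.0)])
    np.testing.assert_allclose(op.matrix, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(op.offset, 0, atol=1e-12)


def test_compose_associativity(rng):
    tissue = TissueParams(900, 45, delta_f=80.0)
    ops = [rotation(35), relaxation(1.25, tissue), precession(1.25, 80.0), rotation(-35), relaxation(3.0, tissue)]
    left = compose([compose(ops[:2]), compose(ops[2:])])
    right = compose([ops[0], compose(ops[1:])])
    m = rng.normal(size=3)
    np.testing.assert_allclose(left(m), right(m), atol=1e-12)


def test_compose_equals_sequential_application(rng):
    tissue = TissueParams(1200, 50, delta_f=-40.0)
    ops = [rotation(a) for a in (10, -35, 90)] + [relaxation(2.0, tissue), precession(2.0, -40.0)]
    m0 = rng.normal(size=3)
    m_seq = m0.copy()
    for op in ops:
        m_seq = op(m_seq)
    np.testing.assert_allclose(compose(ops)(m0), m_seq, atol=1e-12)


@settings(**SETTINGS)
@given(st.floats(10, 5000), st.floats(0.1, 0.99), st.floats(0, 8000))
def test_inversion_recovery_closed_form(t1, mz0_frac, t):
    """With T2 = T1 and no off-resonance the composed relaxation of mz
    follows 1 - (1 - mz(0)) exp(-t/T1) exactly."""
    tissue = TissueParams(t1, t1)
    mz0 = -mz0_frac
    out = relax(t, tissue, MagnetizationState(0, 0, mz0))
    assert out.mz == pytest.approx(1 - (1 - mz0) * math.exp(-t / t1), rel=1e-12, abs=1e-12)


def test_norm_bounded_by_equilibrium_under_random_compositions(rng):
    """Starting from equilibrium, |M| never exceeds M0 under any mix of
    rotations, precessions and (physical, T2 <= T1) relaxations."""
    for _ in range(30):
        t1 = rng.uniform(300, 3000)
        tissue = TissueParams(t1, rng.uniform(20, t1), delta_f=rng.uniform(-200, 200))
        m = MagnetizationState.equilibrium()
        for _ in range(20):
            kind = rng.integers(3)
            if kind == 0:
                m = rotate(rng.uniform(-180, 180), m)
            elif kind == 1:
                m = precess(rng.uniform(0, 10), tissue.delta_f, m)
            else:
                m = relax(rng.uniform(0, 50), tissue, m)
            assert m.norm <= 1.0 + 1e-9


def test_composed_tr_matches_fine_step_integration():
    """One full b-SSFP TR composed as affine operators equals brute-force
    stepping of the free evolution at 1 us resolution."""
    tissue = TissueParams(1180, 45, delta_f=30.0)
    te, tr = 1.25, 2.5
    composed = compose(
        [
            rotation(35.0),
            precession(te, tissue.delta_f),
            relaxation(te, tissue),
            precession(tr - te, tissue.delta_f),
            relaxation(tr - te, tissue),
        ]
    )
    n = 1250  # 1 us steps over each interval
    fine_te = compose([precession(te / n, tissue.delta_f), relaxation(te / n, tissue)])
    fine_rest = compose([precession((tr - te) / n, tissue.delta_f), relaxation((tr - te) / n, tissue)])
    m = np.array([0.1, -0.2, 0.8])
    m_fine = rotation(35.0)(m)
    for _ in range(n):
        m_fine = fine_te(m_fine)
    for _ in range(n):
        m_fine = fine_rest(m_fine)
    np.testing.assert_allclose(composed(m), m_fine, atol=1e-6)
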