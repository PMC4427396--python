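"""Independent reference implementations used as test oracles.

These re-derive the sequence signal by brute-force fine-step integration
built directly on the affine operator objects of :mod:`mollimap.bloch`
(applied one elementary step at a time), independently of the scalar
kernels that power the package's simulators.
"""

from __future__ import annotations

import math

import numpy as np

from mollimap.bloch import TissueParams, precession, relaxation, rotation
from mollimap.sequences import MOLLIProtocol


def free_step_operator(dt: float, tissue: TissueParams):
    """Combined precession+relaxation operator over a small dt as (A, b)."""
    op = precession(dt, tissue.delta_f).then(relaxation(dt, tissue))
    return op.matrix, op.offset


def _substep(m, A, b, n):
    for _ in range(n):
        m = A @ m + b
    return m


def brute_force_readout(
    state: np.ndarray,
    tissue: TissueParams,
    alpha_deg: float,
    protocol,
    dt: float = 0.01,
):
    """Fine-step b-SSFP readout; returns (signal, post_state)."""
    m = np.asarray(state, dtype=float).copy()
    sign = 1.0 if m[2] >= 0 else -1.0
    n_te = max(int(round(protocol.te / dt)), 1)
    n_rest = max(int(round((protocol.tr - protocol.te) / dt)), 1)
    A_te, b_te = free_step_operator(protocol.te / n_te, tissue)
    A_rest, b_rest = free_step_operator((protocol.tr - protocol.te) / n_rest, tissue)
    sig = 0.0
    for scale in protocol.prep_scale_factors:
        m = rotation(scale * alpha_deg).matrix @ m
        m = _substep(m, A_te, b_te, n_te)
        m = _substep(m, A_rest, b_rest, n_rest)
    s = -1.0 if (protocol.prep_scale_factors and protocol.prep_scale_factors[-1] > 0) else 1.0
    for j in range(protocol.n_readout_pulses):
        m = rotation(s * alpha_deg).matrix @ m
        s = -s
        m = _substep(m, A_te, b_te, n_te)
        if j == protocol.center_line_index:
            sig = sign * math.hypot(m[0], m[1])
        m = _substep(m, A_rest, b_rest, n_rest)
    return sig, m


def brute_force_molli(
    tissue: TissueParams,
    protocol: MOLLIProtocol,
    eta: float = 1.0,
    alpha_deg: float | None = None,
    dt: float = 0.01,
    free_dt: float = 1.0,
) -> np.ndarray:
    """Fine-step simulation of the full acquisition (signals in acq. order).

    Readout intervals are stepped at ``dt`` ms; the long free-recovery
    gaps at ``free_dt`` ms.
    """
    if alpha_deg is None:
        alpha_deg = protocol.alpha_nominal
    kinds, times, _ = protocol._timeline()
    m = np.array([0.0, 0.0, tissue.m0])
    t = 0.0
    signals = []
    for kind, t_event in zip(kinds, times):
        gap = t_event - t
        if gap > 0:
            n = max(int(round(gap / free_dt)), 1)
            A, b = free_step_operator(gap / n, tissue)
            m = _substep(m, A, b, n)
        t = t_event
        if kind == 0:
            m = np.array([0.0, 0.0, -eta * m[2]])
        else:
            sig, m = brute_force_readout(m, tissue, alpha_deg, protocol, dt)
            signals.append(sig)
            t += protocol.readout_duration
    return np.array(signals)


def grid_search_three_param(ti, signal, t1_star_grid):
    """Dense-grid least-squares oracle for the 3-parameter exponential fit.

    For each candidate T1* the linear parameters (A, B) are solved in
    closed form; returns (a, b, t1_star) at the global grid minimum.
    """
    ti = np.asarray(ti, dtype=float)
    y = np.asarray(signal, dtype=float)
    best = (None, math.inf)
    for t1s in t1_star_grid:
        x = np.exp(-ti / t1s)
        X = np.column_stack([np.ones_like(x), -x])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((X @ coef - y) ** 2))
        if rss < best[1]:
            best = ((float(coef[0]), float(coef[1]), float(t1s)), rss)
    return best[0]
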