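"""Scalar propagation kernels shared by the sequence simulators.

These are the hot loops: a full ECG-gated acquisition is a few thousand
elementary steps and sits inside Nelder-Mead fits and Monte Carlo loops,
so the state is carried as plain floats (mx, my, mz) rather than operator
objects.  Numerically these kernels are exactly equivalent to composing
the affine operators of :mod:`mollimap.bloch`; the test suite checks the
equivalence against fine-step integration.

Compiled with numba when available; plain Python otherwise.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


TWO_PI = 2.0 * math.pi

# Event codes used by molli_kernel
EV_INVERSION = 0
EV_READOUT = 1


@njit
def _free(mx, my, mz, dt, t1, t2, df, m0):
    """Free precession + relaxation over dt (ms)."""
    e2 = math.exp(-dt / t2)
    e1 = math.exp(-dt / t1)
    theta = TWO_PI * df * dt * 1e-3
    c = math.cos(theta)
    s = math.sin(theta)
    nmx = e2 * (c * mx + s * my)
    nmy = e2 * (-s * mx + c * my)
    nmz = m0 + (mz - m0) * e1
    return nmx, nmy, nmz


@njit
def _pulse(mx, my, mz, a_rad):
    """Instantaneous nutation about x by a_rad radians."""
    c = math.cos(a_rad)
    s = math.sin(a_rad)
    return mx, c * my + s * mz, -s * my + c * mz


@njit
def bssfp_readout_kernel(
    mx,
    my,
    mz,
    t1,
    t2,
    df,
    m0,
    alpha_rad,
    prep_scales,
    n_read,
    center_idx,
    tr,
    te,
):
    """One single-shot b-SSFP readout.

    Applies the flip-angle preparation ramp (prep_scales * alpha, each
    followed by TR of free evolution), then the +/-alpha pulse train with
    the echo sampled TE after each pulse.  Returns the signed center-line
    signal (|Mxy| at the center echo, signed by the polarity of Mz at
    readout start) and the final state.
    """
    sign = 1.0 if mz >= 0.0 else -1.0
    n_prep = prep_scales.shape[0]
    for k in range(n_prep):
        mx, my, mz = _pulse(mx, my, mz, prep_scales[k] * alpha_rad)
        mx, my, mz = _free(mx, my, mz, tr, t1, t2, df, m0)
    # Train sign continues the alternation of the ramp.
    if n_prep > 0 and prep_scales[n_prep - 1] > 0.0:
        s = -1.0
    else:
        s = 1.0
    sig = 0.0
    for j in range(n_read):
        mx, my, mz = _pulse(mx, my, mz, s * alpha_rad)
        s = -s
        mx, my, mz = _free(mx, my, mz, te, t1, t2, df, m0)
        if j == center_idx:
            sig = sign * math.hypot(mx, my)
        mx, my, mz = _free(mx, my, mz, tr - te, t1, t2, df, m0)
    return sig, mx, my, mz


@njit
def molli_kernel(
    t1,
    t2,
    df,
    m0,
    eta,
    alpha_rad,
    prep_scales,
    n_read,
    center_idx,
    tr,
    te,
    event_kind,
    event_time,
    n_images,
):
    """Propagate a full inversion-recovery acquisition.

    ``event_kind``/``event_time`` is the chronologically sorted event list:
    kind 0 = instantaneous inversion (Mz -> -eta*Mz, transverse spoiled),
    kind 1 = b-SSFP readout starting at the given time.  Free precession
    and relaxation fill the gaps.  Returns the center-line signal of each
    readout in acquisition order.
    """
    mx, my, mz = 0.0, 0.0, m0
    t = 0.0
    readout_dur = (prep_scales.shape[0] + n_read) * tr
    signals = np.zeros(n_images)
    i_img = 0
    for e in range(event_kind.shape[0]):
        dt = event_time[e] - t
        if dt > 0.0:
            mx, my, mz = _free(mx, my, mz, dt, t1, t2, df, m0)
        t = event_time[e]
        if event_kind[e] == EV_INVERSION:
            mx = 0.0
            my = 0.0
            mz = -eta * mz
        else:
            sig, mx, my, mz = bssfp_readout_kernel(
                mx, my, mz, t1, t2, df, m0, alpha_rad, prep_scales, n_read, center_idx, tr, te
            )
            signals[i_img] = sig
            i_img += 1
            t += readout_dur
    return signals
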