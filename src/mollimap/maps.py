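"""Auxiliary parameter maps: T2, B1+ (flip angle) and gold-standard IR T1.

The simulation-based MOLLI fit needs per-pixel T2 and achieved flip angle
as fixed inputs.  This module provides the corresponding estimators:
mono-exponential T2 fits (T2-prepared b-SSFP in vivo, multi-TE spin echo
in vitro), the 3-parameter inversion-recovery fit used as the phantom
gold standard, and the conversion of Bloch-Siegert phase maps to achieved
flip angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fitting import FitResult, ThreeParamFit, fit_three_param

__all__ = [
    "ParameterMap",
    "BlochSiegertParams",
    "MonoExpResult",
    "fit_t2prep",
    "fit_t2_se",
    "fit_ir",
    "bloch_siegert_phase",
    "bloch_siegert_to_alpha",
]

# 1H gyromagnetic ratio in rad/s per uT.
GAMMA_RAD_PER_S_UT = 2.0 * math.pi * 42.577478


@dataclass
class ParameterMap:
    """2D gridded parameter map with units and a validity mask.

    ``values`` outside the mask are ignored by the masked statistics.
    """

    values: np.ndarray
    units: str = "ms"
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask and values must have congruent shapes")

    @property
    def shape(self):
        return self.values.shape

    def masked(self) -> np.ndarray:
        return self.values[self.mask]

    def mean(self) -> float:
        return float(np.nanmean(self.masked()))

    def std(self) -> float:
        return float(np.nanstd(self.masked()))

    def with_nodata(self, fill=np.nan) -> np.ndarray:
        out = np.full(self.values.shape, fill, dtype=float)
        out[self.mask] = self.values[self.mask]
        return out


@dataclass
class BlochSiegertParams:
    """Off-resonance Fermi pulse used for Bloch-Siegert B1+ mapping.

    delta_omega is the RF offset in kHz (the two acquisitions use +/-
    delta_omega); flip is the on-resonance flip angle the pulse would
    produce, which fixes the nominal peak amplitude.  Fermi envelope
    constants t0 (flat-top half-width) and a (transition width) default
    to 0.6*duration/2 and duration/70.
    """

    delta_omega: float = 8.0
    pulse_duration: float = 8.0
    pulse_flip: float = 600.0
    shape: str = "fermi"
    t0: float | None = None
    a: float | None = None
    dt: float = 0.001

    def __post_init__(self) -> None:
        if self.delta_omega == 0:
            raise ValueError("delta_omega must be non-zero")
        if self.t0 is None:
            self.t0 = 0.6 * self.pulse_duration / 2.0
        if self.a is None:
            self.a = self.pulse_duration / 70.0

    def envelope(self):
        """Normalized (unit peak) Fermi envelope sampled at step dt (ms)."""
        n = max(int(round(self.pulse_duration / self.dt)), 10)
        t = (np.arange(n) + 0.5) * (self.pulse_duration / n)
        env = 1.0 / (1.0 + np.exp((np.abs(t - self.pulse_duration / 2.0) - self.t0) / self.a))
        return env / env.max(), self.pulse_duration / n

    @property
    def nominal_peak_b1(self) -> float:
        """Peak B1 (uT) delivering the stated on-resonance flip angle."""
        env, dt = self.envelope()
        area_s = float(np.sum(env)) * dt * 1e-3  # s
        return math.radians(self.pulse_flip) / (GAMMA_RAD_PER_S_UT * area_s)

    @property
    def k_bs(self) -> float:
        """Phase constant: phi_BS = k_bs * B1peak^2 (rad per uT^2).

        Far-off-resonance approximation phi = int (gamma B1)^2 / (2 d_omega) dt
        for the normalized envelope; the +/- d_omega phase difference is
        2 * k_bs * B1peak^2.
        """
        env, dt = self.envelope()
        dw = 2.0 * math.pi * abs(self.delta_omega) * 1e3  # rad/s
        integ = float(np.sum(env**2)) * dt * 1e-3  # s
        return GAMMA_RAD_PER_S_UT**2 * integ / (2.0 * dw)


@dataclass
class MonoExpResult:
    """Result of a mono-exponential decay fit S = S0 exp(-t/tau)."""

    tau: float
    s0: float
    ok: bool


def _loglinear_decay(signals, times) -> MonoExpResult:
    s = np.asarray(signals, dtype=float)
    t = np.asarray(times, dtype=float)
    if np.any(s <= 0):
        raise ValueError("signals must be positive for a log-linear decay fit")
    if s.size < 2:
        raise ValueError("need at least 2 samples")
    # Weighted (by signal^2) linear LS on ln S = ln S0 - t/tau.
    w = s**2
    y = np.log(s)
    W = np.sum(w)
    tbar = np.sum(w * t) / W
    ybar = np.sum(w * y) / W
    denom = np.sum(w * (t - tbar) ** 2)
    if denom == 0:
        raise ValueError("degenerate time points")
    slope = np.sum(w * (t - tbar) * (y - ybar)) / denom
    s0 = math.exp(ybar - slope * tbar)
    if slope >= 0:
        # Non-decaying signals: no finite positive tau.
        return MonoExpResult(math.inf, s0, False)
    return MonoExpResult(-1.0 / slope, s0, True)


def fit_t2prep(signals, prep_times) -> MonoExpResult:
    """T2 from T2-prepared b-SSFP signals at the given preparation times.

    Log-linear (signal^2-weighted) mono-exponential fit; with the default
    three preparation times this uses exactly the information available
    and is deterministic.  Non-decaying input returns ok=False with
    tau=inf.
    """
    return _loglinear_decay(signals, prep_times)


def fit_t2_se(signals, te) -> MonoExpResult:
    """T2 from a multi-echo spin-echo series (the in vitro gold standard)."""
    s = np.asarray(signals, dtype=float)
    if s.size < 3:
        raise ValueError("need at least 3 echoes")
    return _loglinear_decay(s, te)


def fit_ir(signals, ti, is_magnitude: bool = False) -> FitResult:
    """Gold-standard inversion-recovery T1 fit S = A - B exp(-TI/T1).

    No Look-Locker correction is applied: the readout is assumed not to
    perturb the recovery (TR much longer than T1, one line per inversion).
    Polarity restoration is applied to magnitude data.
    """
    fit, n_evals = fit_three_param(ti, signals, is_magnitude)
    if fit is None:
        return FitResult(math.nan, False, n_evals, math.inf, "ir", None, ("no-convergence",))
    if fit.a <= 0 or fit.t1_star <= 0:
        return FitResult(math.nan, False, n_evals, fit.rss, "ir", fit, ("unphysical",))
    return FitResult(fit.t1_star, True, n_evals, fit.rss, "ir", fit)


def bloch_siegert_phase(b1_peak, params: BlochSiegertParams | None = None) -> np.ndarray:
    """Forward model: +/- delta_omega phase difference (rad) for a peak B1 (uT).

    Scalar or array input.  phi_diff = 2 * k_bs * B1peak^2.
    """
    if params is None:
        params = BlochSiegertParams()
    b1 = np.asarray(b1_peak, dtype=float)
    return 2.0 * params.k_bs * b1**2


def bloch_siegert_to_alpha(
    phase_diff,
    params: BlochSiegertParams | None = None,
    nominal_alpha: float = 35.0,
    b1_nominal: float | None = None,
    mask: np.ndarray | None = None,
) -> ParameterMap:
    """Achieved excitation flip angle from a Bloch-Siegert phase map.

    ``phase_diff`` is the unwrapped phase difference between the +delta_omega
    and -delta_omega acquisitions (radians).  Peak B1 = sqrt(phi / (2 k_bs));
    the achieved flip angle is nominal_alpha * B1 / B1_nominal where
    B1_nominal defaults to the pulse amplitude delivering the stated
    600 deg Fermi flip.  Pixels with negative phase are masked out.
    """
    if params is None:
        params = BlochSiegertParams()
    phi = np.asarray(phase_diff, dtype=float)
    if b1_nominal is None:
        b1_nominal = params.nominal_peak_b1
    if mask is None:
        mask = np.isfinite(phi)
    valid = mask & (phi >= 0)
    b1 = np.full(phi.shape, np.nan)
    b1[valid] = np.sqrt(phi[valid] / (2.0 * params.k_bs))
    alpha = nominal_alpha * b1 / b1_nominal
    return ParameterMap(values=alpha, units="degrees", mask=valid,
                        meta={"delta_omega_khz": params.delta_omega,
                              "pulse_flip_deg": params.pulse_flip,
                              "nominal_alpha_deg": nominal_alpha})
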