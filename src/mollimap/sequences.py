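"""Forward simulation of ECG-gated MOLLI and T2-prepared b-SSFP acquisitions.

The MOLLI (Modified Look-Locker Inversion recovery) sequence acquires
single-shot b-SSFP images over several cardiac cycles: three inversions
followed by blocks of 3, 3 and 5 images at one image per R-R interval,
with rest periods between blocks.  Given tissue parameters, inversion
efficacy eta and the achieved flip angle, the simulator returns the
signal sampled at the k-space center line of each image -- the function
f(T1, T2, eta, alpha, t) evaluated at the 11 inversion times -- which is
both the forward model of the simulation-based fit and the generator of
all synthetic data in this package.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .bloch import MagnetizationState, TissueParams
from . import _kernel

__all__ = [
    "MOLLIProtocol",
    "T2PrepProtocol",
    "RecoveryCurve",
    "simulate_bssfp_readout",
    "simulate_molli",
    "simulate_t2prep_bssfp",
]

# Flip-angle preparation ramp preceding the pulse train: fractions of the
# nominal flip angle, alternating sign, one per TR.
DEFAULT_PREP_SCALES = (1.0 / 6.0, -1.0 / 3.0, 1.0 / 2.0, -2.0 / 3.0, 5.0 / 6.0)


@dataclass
class MOLLIProtocol:
    """Complete timing / flip-angle description of one MOLLI acquisition.

    Times in ms, angles in degrees.  Defaults reproduce the standard
    3(3)3(3)5 protocol at 60 bpm: TI1 = 100 ms, dTI = 80 ms,
    TE/TR = 1.25/2.5 ms, nominal flip angle 35 deg, 69-pulse readout train
    with 5 ramp pulses, center line acquired as pulse 24 of the train
    (linear ordering with 75% partial Fourier).
    """

    ti1: float = 100.0
    delta_ti: float = 80.0
    tr: float = 2.5
    te: float = 1.25
    alpha_nominal: float = 35.0
    scheme: tuple = (3, 3, 5)
    rest_periods: tuple = (3, 3)
    rr_interval: float = 1000.0
    n_readout_pulses: int = 69
    n_prep_pulses: int = 5
    prep_scale_factors: tuple = DEFAULT_PREP_SCALES
    center_line_index: int = 23

    def __post_init__(self) -> None:
        self.scheme = tuple(int(n) for n in self.scheme)
        self.rest_periods = tuple(int(n) for n in self.rest_periods)
        self.prep_scale_factors = tuple(float(s) for s in self.prep_scale_factors)
        if any(n <= 0 for n in self.scheme):
            raise ValueError(f"scheme blocks must be positive, got {self.scheme}")
        if len(self.rest_periods) < len(self.scheme) - 1:
            raise ValueError("need a rest period count for each inter-block gap")
        if any(r < 0 for r in self.rest_periods):
            raise ValueError("rest periods must be non-negative R-R counts")
        if len(self.prep_scale_factors) != self.n_prep_pulses:
            raise ValueError("prep_scale_factors length must equal n_prep_pulses")
        if not 0 <= self.center_line_index < self.n_readout_pulses:
            raise ValueError("center_line_index outside the readout train")
        if self.te <= 0 or self.tr <= self.te:
            raise ValueError("need 0 < TE < TR")

    @property
    def n_images(self) -> int:
        return sum(self.scheme)

    @property
    def readout_duration(self) -> float:
        """Duration of one single-shot readout (ramp + train), ms."""
        return (self.n_prep_pulses + self.n_readout_pulses) * self.tr

    @property
    def time_to_center(self) -> float:
        """Delay from readout start to the center-line echo, ms."""
        return (self.n_prep_pulses + self.center_line_index) * self.tr + self.te

    def inversion_times(self) -> np.ndarray:
        """TIs of the images in acquisition order (ms)."""
        _, _, tis = self._timeline()
        return tis

    def _timeline(self):
        """Chronological event list for the kernel.

        Returns (event_kind, event_time, tis): inversion and readout-start
        events referenced to the first inversion at t = 0, plus the TI of
        each image in acquisition order.  Image center lines are locked to
        the cardiac phase grid c * RR + TI1 (constant R-R, no ECG jitter).
        """
        t_pre = self.time_to_center
        kinds, times, tis = [], [], []
        cycle = 0
        prev_end = 0.0
        for b, n_img in enumerate(self.scheme):
            ti_b = self.ti1 + b * self.delta_ti
            if ti_b - t_pre < 0:
                raise ValueError(
                    f"TI{b + 1} = {ti_b} ms leaves a negative inversion-to-"
                    f"readout delay (center line is {t_pre} ms into the readout)"
                )
            t_first_center = cycle * self.rr_interval + self.ti1
            t_inv = t_first_center - ti_b
            if t_inv < prev_end:
                raise ValueError(
                    f"inversion of block {b + 1} at t = {t_inv} ms overlaps the "
                    "previous readout; increase rest periods or rr_interval"
                )
            kinds.append(_kernel.EV_INVERSION)
            times.append(t_inv)
            for i in range(n_img):
                t_center = (cycle + i) * self.rr_interval + self.ti1
                t_start = t_center - t_pre
                if t_start + 1e-9 < prev_end:
                    raise ValueError(
                        f"readout starting at t = {t_start} ms overlaps the "
                        "previous readout; rr_interval too short for the readout"
                    )
                kinds.append(_kernel.EV_READOUT)
                times.append(t_start)
                tis.append(t_center - t_inv)
                prev_end = t_start + self.readout_duration
            cycle += n_img
            if b < len(self.scheme) - 1:
                cycle += self.rest_periods[b]
        return (
            np.array(kinds, dtype=np.int64),
            np.array(times, dtype=np.float64),
            np.array(tis, dtype=np.float64),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scheme"] = list(self.scheme)
        d["rest_periods"] = list(self.rest_periods)
        d["prep_scale_factors"] = list(self.prep_scale_factors)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MOLLIProtocol":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "MOLLIProtocol":
        return cls.from_dict(json.loads(s))


@dataclass
class T2PrepProtocol:
    """T2-prepared b-SSFP protocol: the in vivo T2-mapping acquisition."""

    prep_times: tuple = (0.0, 25.0, 75.0)
    tr: float = 2.6
    te: float = 1.3
    alpha: float = 35.0
    rest_rr: int = 3
    rr_interval: float = 1000.0
    n_readout_pulses: int = 69
    n_prep_pulses: int = 5
    prep_scale_factors: tuple = DEFAULT_PREP_SCALES
    center_line_index: int = 23

    def __post_init__(self) -> None:
        self.prep_times = tuple(float(t) for t in self.prep_times)
        if any(t < 0 for t in self.prep_times):
            raise ValueError("prep_times must be non-negative")
        if any(b >= a for a, b in zip(self.prep_times[1:], self.prep_times)):
            raise ValueError("prep_times must be strictly increasing")

    @property
    def readout_duration(self) -> float:
        return (self.n_prep_pulses + self.n_readout_pulses) * self.tr

    def to_dict(self) -> dict:
        d = asdict(self)
        d["prep_times"] = list(self.prep_times)
        d["prep_scale_factors"] = list(self.prep_scale_factors)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "T2PrepProtocol":
        return cls(**d)


@dataclass
class RecoveryCurve:
    """Sampled inversion-recovery curve: (TI, signal) pairs.

    ``signal`` is the signed center-line amplitude (phase-sensitive
    convention) unless ``is_magnitude`` is set, in which case values are
    absolute as stored by scanner magnitude images.  ``order`` maps the
    stored (acquisition) order to TI-sorted order.
    """

    ti: np.ndarray
    signal: np.ndarray
    is_magnitude: bool = False

    def __post_init__(self) -> None:
        self.ti = np.asarray(self.ti, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.ti.shape != self.signal.shape:
            raise ValueError("ti and signal must have equal length")
        if np.any(self.ti <= 0):
            raise ValueError("inversion times must be strictly positive")

    def __len__(self) -> int:
        return self.ti.size

    @property
    def order(self) -> np.ndarray:
        return np.argsort(self.ti, kind="stable")

    def sorted(self) -> "RecoveryCurve":
        """Return a copy reordered by increasing TI."""
        idx = self.order
        return RecoveryCurve(self.ti[idx], self.signal[idx], self.is_magnitude)

    def to_magnitude(self) -> "RecoveryCurve":
        return RecoveryCurve(self.ti.copy(), np.abs(self.signal), True)


def _check_alpha(alpha_deg: float, prep_scales) -> None:
    worst = max(1.0, max(abs(s) for s in prep_scales) if len(prep_scales) else 1.0)
    if abs(alpha_deg) * worst > 360.0:
        raise ValueError(
            f"flip angle {alpha_deg} deg drives a pulse beyond 360 deg; "
            "protocol misconfiguration"
        )


def simulate_bssfp_readout(
    tissue: TissueParams,
    alpha_deg: float,
    protocol,
    state: MagnetizationState | None = None,
):
    """Single-shot b-SSFP readout from an arbitrary starting state.

    ``protocol`` supplies tr, te, prep_scale_factors, n_readout_pulses and
    center_line_index (MOLLIProtocol and T2PrepProtocol both work).
    Returns (signal, post_state) where signal is the signed center-line
    amplitude.
    """
    if state is None:
        state = MagnetizationState.equilibrium(tissue.m0)
    prep = np.asarray(protocol.prep_scale_factors, dtype=float)
    _check_alpha(alpha_deg, prep)
    sig, mx, my, mz = _kernel.bssfp_readout_kernel(
        state.mx,
        state.my,
        state.mz,
        tissue.t1,
        tissue.t2,
        tissue.delta_f,
        tissue.m0,
        math.radians(alpha_deg),
        prep,
        protocol.n_readout_pulses,
        protocol.center_line_index,
        protocol.tr,
        protocol.te,
    )
    return sig, MagnetizationState(mx, my, mz)


def simulate_molli(
    tissue: TissueParams,
    protocol: MOLLIProtocol | None = None,
    eta: float = 1.0,
    alpha_actual: float | None = None,
) -> RecoveryCurve:
    """Simulate one full MOLLI acquisition for one pixel.

    Starting from equilibrium: inversion with efficacy ``eta``
    (instantaneous Mz -> -eta*Mz, transverse spoiled), readouts locked to
    the cardiac phase so each image's center line falls at its nominal TI,
    free relaxation during rest periods, re-inversions before later blocks
    with TI_b = TI1 + (b-1)*dTI.  Returns the (TI, signal) samples in
    acquisition order.

    ``alpha_actual`` is the achieved readout flip angle (defaults to the
    protocol's nominal value); eta in (0, 1].
    """
    if protocol is None:
        protocol = MOLLIProtocol()
    if not 0.0 < eta <= 1.0:
        raise ValueError(f"eta must be in (0, 1], got {eta}")
    if alpha_actual is None:
        alpha_actual = protocol.alpha_nominal
    prep = np.asarray(protocol.prep_scale_factors, dtype=float)
    _check_alpha(alpha_actual, prep)
    kinds, times, tis = protocol._timeline()
    signals = _kernel.molli_kernel(
        tissue.t1,
        tissue.t2,
        tissue.delta_f,
        tissue.m0,
        eta,
        math.radians(alpha_actual),
        prep,
        protocol.n_readout_pulses,
        protocol.center_line_index,
        protocol.tr,
        protocol.te,
        kinds,
        times,
        protocol.n_images,
    )
    return RecoveryCurve(tis, signals)


def simulate_t2prep_bssfp(
    tissue: TissueParams,
    protocol: T2PrepProtocol | None = None,
) -> list:
    """Simulate the T2-prepared b-SSFP acquisition.

    For each preparation time: ideal T2 preparation (Mz -> Mz *
    exp(-t_prep/T2), transverse spoiled), b-SSFP readout, then ``rest_rr``
    R-R intervals of free recovery before the next preparation.  Returns
    [(prep_time, signal), ...].
    """
    if protocol is None:
        protocol = T2PrepProtocol()
    state = MagnetizationState.equilibrium(tissue.m0)
    cycle_len = (1 + protocol.rest_rr) * protocol.rr_interval
    out = []
    for tp in protocol.prep_times:
        mz = state.mz * math.exp(-tp / tissue.t2)
        state = MagnetizationState(0.0, 0.0, mz)
        sig, state = simulate_bssfp_readout(tissue, protocol.alpha, protocol, state)
        out.append((tp, sig))
        t_free = cycle_len - tp - protocol.readout_duration
        if t_free < 0:
            raise ValueError("preparation + readout exceed the acquisition cycle")
        mx, my, mz = _kernel._free(
            state.mx, state.my, state.mz, t_free, tissue.t1, tissue.t2, tissue.delta_f, tissue.m0
        )
        state = MagnetizationState(mx, my, mz)
    return out
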