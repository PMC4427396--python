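"""Synthetic digital phantoms and forward-simulated acquisitions.

Stands in for scanner data end to end: a six-tube agar phantom whose
ground-truth T1/T2 reproduce the physical calibration phantom, and
myocardium-like uniform maps; both can be "acquired" with the MOLLI,
T2-prepared b-SSFP and Bloch-Siegert forward models plus Gaussian (or
Rician) noise, yielding image stacks with JSON-style sidecar metadata.

Image formation is per-pixel signal simulation: the analyses downstream
operate on per-pixel recovery curves, so k-space/PSF effects are outside
the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bloch import TissueParams
from .maps import BlochSiegertParams, ParameterMap, bloch_siegert_phase
from .sequences import MOLLIProtocol, T2PrepProtocol, simulate_molli, simulate_t2prep_bssfp

__all__ = [
    "DigitalPhantom",
    "TUBE_T1",
    "TUBE_T2",
    "make_tube_phantom",
    "make_myocardium_phantom",
    "acquire",
    "estimate_noise_sigma",
]

# Ground-truth relaxation times of the six Gd-DOTA-doped agar tubes
# (gold-standard IR-TSE / multi-echo SE values).
TUBE_T1 = (2085.0, 1747.0, 1422.0, 1038.0, 706.0, 535.0)
TUBE_T2 = (43.5, 42.9, 42.9, 42.8, 42.1, 41.8)


@dataclass
class DigitalPhantom:
    """Congruent ground-truth parameter maps plus an integer label grid.

    Label 0 is background (m0 = 0, excluded from every mask).
    """

    t1: ParameterMap
    t2: ParameterMap
    b0: ParameterMap
    b1_scale: ParameterMap
    m0: ParameterMap
    labels: np.ndarray

    def __post_init__(self) -> None:
        shape = self.labels.shape
        for name in ("t1", "t2", "b0", "b1_scale", "m0"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} map not congruent with labels grid")

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def roi_mean(self, values: np.ndarray, label: int) -> float:
        return float(np.nanmean(values[self.labels == label]))


def _b1_field(shape, profile, rng):
    ny, nx = shape
    if profile is None or profile == "uniform":
        return np.ones(shape)
    if profile == "gradient":
        # Smooth left-to-right transmit-field increase, like the
        # right-to-left ventricle pattern seen in vivo.
        ramp = np.linspace(0.9, 1.1, nx)
        return np.tile(ramp, (ny, 1))
    if np.isscalar(profile):
        return np.full(shape, float(profile))
    arr = np.asarray(profile, dtype=float)
    if arr.shape != shape:
        raise ValueError("b1 profile array must match the grid")
    return arr


def make_tube_phantom(
    t1_list=TUBE_T1,
    t2_list=TUBE_T2,
    grid: int = 64,
    b1_profile="uniform",
    seed: int | None = None,
) -> DigitalPhantom:
    """Circular tubes on a square grid with the given ground-truth values.

    Tubes are laid out on a 2 x ceil(n/2) lattice; a seeded RNG jitters
    the centers by up to one pixel (bit-reproducible for a given seed).
    Overlapping tubes raise.
    """
    t1_list = tuple(float(v) for v in t1_list)
    t2_list = tuple(float(v) for v in t2_list)
    if len(t1_list) != len(t2_list):
        raise ValueError("t1_list and t2_list must have equal length")
    n = len(t1_list)
    rng = np.random.default_rng(seed)
    ncol = math.ceil(n / 2) if n > 1 else 1
    nrow = 2 if n > 1 else 1
    radius = grid / (2.5 * max(ncol, nrow))
    centers = []
    for k in range(n):
        r, c = divmod(k, ncol)
        cy = (r + 0.5) * grid / nrow + rng.uniform(-1, 1)
        cx = (c + 0.5) * grid / ncol + rng.uniform(-1, 1)
        centers.append((cy, cx))
    for i in range(n):
        for j in range(i + 1, n):
            d = math.hypot(centers[i][0] - centers[j][0], centers[i][1] - centers[j][1])
            if d < 2 * radius:
                raise ValueError(f"tubes {i + 1} and {j + 1} overlap")
    yy, xx = np.mgrid[0:grid, 0:grid]
    labels = np.zeros((grid, grid), dtype=int)
    t1 = np.full((grid, grid), np.nan)
    t2 = np.full((grid, grid), np.nan)
    for k, (cy, cx) in enumerate(centers):
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        labels[inside] = k + 1
        t1[inside] = t1_list[k]
        t2[inside] = t2_list[k]
    mask = labels > 0
    m0 = np.where(mask, 1.0, 0.0)
    b1 = _b1_field((grid, grid), b1_profile, rng)
    b0 = np.zeros((grid, grid))
    meta = {"kind": "tube-phantom", "seed": seed, "grid": grid}
    return DigitalPhantom(
        t1=ParameterMap(t1, "ms", mask, meta),
        t2=ParameterMap(t2, "ms", mask, meta),
        b0=ParameterMap(b0, "Hz", mask, meta),
        b1_scale=ParameterMap(b1, "dimensionless", mask, meta),
        m0=ParameterMap(m0, "dimensionless", mask, meta),
        labels=labels,
    )


def make_myocardium_phantom(
    t1: float = 1410.0,
    t2: float = 41.0,
    grid: int = 64,
    b1_profile="gradient",
    seed: int | None = None,
) -> DigitalPhantom:
    """Myocardium-like uniform-tissue disc with an in-vivo-style B1 gradient."""
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:grid, 0:grid]
    c = (grid - 1) / 2.0
    inside = (yy - c) ** 2 + (xx - c) ** 2 <= (0.4 * grid) ** 2
    labels = inside.astype(int)
    meta = {"kind": "myocardium-phantom", "seed": seed, "grid": grid}
    mk = lambda v, u: ParameterMap(np.where(inside, v, np.nan), u, inside, meta)
    return DigitalPhantom(
        t1=mk(t1, "ms"),
        t2=mk(t2, "ms"),
        b0=ParameterMap(np.zeros((grid, grid)), "Hz", inside, meta),
        b1_scale=ParameterMap(_b1_field((grid, grid), b1_profile, rng), "dimensionless", inside, meta),
        m0=ParameterMap(labels.astype(float), "dimensionless", inside, meta),
        labels=labels,
    )


def estimate_noise_sigma(stack: np.ndarray, background: np.ndarray) -> float:
    """Noise standard deviation estimated from background pixels."""
    return float(np.std(stack[background]))


def _simulate_pixel_group(kind, t1, t2, alpha, eta, protocol):
    if kind == "molli":
        curve = simulate_molli(TissueParams(t1, t2), protocol, eta=eta, alpha_actual=alpha)
        return curve.signal
    out = simulate_t2prep_bssfp(
        TissueParams(t1, t2),
        T2PrepProtocol(
            prep_times=protocol.prep_times,
            tr=protocol.tr,
            te=protocol.te,
            alpha=alpha,
            rest_rr=protocol.rest_rr,
            rr_interval=protocol.rr_interval,
            n_readout_pulses=protocol.n_readout_pulses,
            n_prep_pulses=protocol.n_prep_pulses,
            prep_scale_factors=protocol.prep_scale_factors,
            center_line_index=protocol.center_line_index,
        ),
    )
    return np.array([s for _, s in out])


def acquire(
    phantom: DigitalPhantom,
    protocol,
    snr: float = math.inf,
    seed: int | None = None,
    eta: float = 0.92,
    noise_model: str = "gaussian",
):
    """Forward-simulate an acquisition of the phantom.

    ``protocol`` selects the model: MOLLIProtocol or T2PrepProtocol give a
    per-pixel image stack of shape (ny, nx, n_images); BlochSiegertParams
    gives the (ny, nx) phase-difference image.  Each pixel uses its own
    (T1, T2, B1 scale); the achieved readout flip angle is the nominal
    value scaled by the B1+ map.  Gaussian noise of standard deviation
    m0_max/snr is added everywhere (Rician: magnitude of complex Gaussian
    noise around the signal).  Returns (stack, meta) where meta carries
    TIs / prep times, protocol, seed and snr.
    """
    rng = np.random.default_rng(seed)
    labels = phantom.labels
    ny, nx = labels.shape
    mask = phantom.mask
    m0max = float(np.nanmax(phantom.m0.values)) or 1.0
    sigma = 0.0 if math.isinf(snr) else m0max / snr

    if isinstance(protocol, BlochSiegertParams):
        b1_nom = protocol.nominal_peak_b1
        phase = np.zeros((ny, nx))
        phase[mask] = bloch_siegert_phase(phantom.b1_scale.values[mask] * b1_nom, protocol)
        if sigma:
            phase = phase + rng.normal(0.0, sigma, phase.shape)
        meta = {"kind": "bloch_siegert", "seed": seed, "snr": snr,
                "params": {"delta_omega": protocol.delta_omega,
                           "pulse_duration": protocol.pulse_duration,
                           "pulse_flip": protocol.pulse_flip}}
        return phase, meta

    if isinstance(protocol, MOLLIProtocol):
        kind = "molli"
        n_img = protocol.n_images
        times = protocol.inversion_times().tolist()
        alpha_nom = protocol.alpha_nominal
    elif isinstance(protocol, T2PrepProtocol):
        kind = "t2prep"
        n_img = len(protocol.prep_times)
        times = list(protocol.prep_times)
        alpha_nom = protocol.alpha
    else:
        raise TypeError(f"unsupported protocol type {type(protocol).__name__}")

    stack = np.zeros((ny, nx, n_img))
    # Pixels sharing (T1, T2, alpha) are simulated once.
    t1v, t2v = phantom.t1.values, phantom.t2.values
    alphav = alpha_nom * phantom.b1_scale.values
    keys = np.stack([t1v, t2v, np.round(alphav, 6)], axis=-1)
    flat_mask = mask.ravel()
    flat_keys = keys.reshape(-1, 3)[flat_mask]
    uniq, inverse = np.unique(flat_keys, axis=0, return_inverse=True)
    sigs = np.empty((uniq.shape[0], n_img))
    for i, (t1, t2, alpha) in enumerate(uniq):
        sigs[i] = _simulate_pixel_group(kind, t1, t2, alpha, eta, protocol)
    flat = stack.reshape(-1, n_img)
    flat[flat_mask] = sigs[inverse] * phantom.m0.values.ravel()[flat_mask, None]
    stack = flat.reshape(ny, nx, n_img)
    if sigma:
        if noise_model == "rician":
            stack = np.hypot(stack + rng.normal(0.0, sigma, stack.shape),
                             rng.normal(0.0, sigma, stack.shape))
        else:
            stack = stack + rng.normal(0.0, sigma, stack.shape)
    meta = {
        "kind": kind,
        "times_ms": times,
        "protocol": protocol.to_dict(),
        "seed": seed,
        "snr": None if math.isinf(snr) else snr,
        "eta": eta,
        "noise_model": noise_model,
        "is_magnitude": noise_model == "rician",
    }
    return stack, meta
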