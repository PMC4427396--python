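"""Elementary Bloch operators in affine matrix form.

Magnetization evolution through a pulse sequence is described step by step
by the general matrix recursion ``M_{k+1} = A @ M_k + B`` where ``M_k`` is
the 3-vector (Mx, My, Mz) at step ``k``.  Three elementary operators are
provided, each an affine pair ``(A, B)``:

* :func:`rotation` -- RF nutation of angle alpha about the x-axis,
* :func:`precession` -- free precession about z at off-resonance ``delta_f``,
* :func:`relaxation` -- T1/T2 relaxation toward equilibrium [0, 0, m0].

All sequence simulators in this package are compositions of these three.
Times are milliseconds, frequencies Hz, angles degrees at the API boundary
(radians internally).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MagnetizationState",
    "TissueParams",
    "BlochOperator",
    "identity",
    "rotation",
    "precession",
    "relaxation",
    "compose",
    "rotate",
    "precess",
    "relax",
]


@dataclass
class MagnetizationState:
    """Magnetization 3-vector in units of the equilibrium magnetization."""

    mx: float = 0.0
    my: float = 0.0
    mz: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mx", "my", "mz"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"non-finite magnetization component {name}={v}")

    @classmethod
    def equilibrium(cls, m0: float = 1.0) -> "MagnetizationState":
        return cls(0.0, 0.0, m0)

    @classmethod
    def from_array(cls, arr) -> "MagnetizationState":
        a = np.asarray(arr, dtype=float).reshape(3)
        return cls(float(a[0]), float(a[1]), float(a[2]))

    def as_array(self) -> np.ndarray:
        return np.array([self.mx, self.my, self.mz], dtype=float)

    @property
    def norm(self) -> float:
        return math.sqrt(self.mx**2 + self.my**2 + self.mz**2)

    @property
    def transverse(self) -> float:
        """Magnitude of the transverse component |Mxy|."""
        return math.hypot(self.mx, self.my)


@dataclass
class TissueParams:
    """Relaxation parameters of one pixel / tube.

    t1, t2 in ms; delta_f is the off-resonance frequency in Hz; m0 the
    equilibrium magnetization (amplitude scale, dimensionless).
    """

    t1: float
    t2: float
    delta_f: float = 0.0
    m0: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.t1) and self.t1 > 0):
            raise ValueError(f"t1 must be positive and finite, got {self.t1}")
        if not (math.isfinite(self.t2) and self.t2 > 0):
            raise ValueError(f"t2 must be positive and finite, got {self.t2}")
        if not (math.isfinite(self.m0) and self.m0 > 0):
            raise ValueError(f"m0 must be positive and finite, got {self.m0}")
        if not math.isfinite(self.delta_f):
            raise ValueError(f"delta_f must be finite, got {self.delta_f}")
        if self.t2 > self.t1:
            warnings.warn(
                f"t2 ({self.t2} ms) exceeds t1 ({self.t1} ms); physically "
                "t2 <= t1 for tissues -- simulating anyway",
                stacklevel=2,
            )


@dataclass(frozen=True)
class BlochOperator:
    """Affine operator ``M -> matrix @ M + offset``.

    Composition rule: ``(A2, B2) o (A1, B1) = (A2 A1, A2 B1 + B2)`` where the
    operator with subscript 1 is applied first.
    """

    matrix: np.ndarray
    offset: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float).reshape(3, 3))
        object.__setattr__(self, "offset", np.asarray(self.offset, dtype=float).reshape(3))

    def apply(self, state):
        """Apply to a MagnetizationState or a length-3 array."""
        if isinstance(state, MagnetizationState):
            out = self.matrix @ state.as_array() + self.offset
            return MagnetizationState.from_array(out)
        return self.matrix @ np.asarray(state, dtype=float) + self.offset

    __call__ = apply

    def then(self, other: "BlochOperator") -> "BlochOperator":
        """Return the operator 'self first, then other'."""
        return BlochOperator(other.matrix @ self.matrix, other.matrix @ self.offset + other.offset)


def identity() -> BlochOperator:
    return BlochOperator(np.eye(3), np.zeros(3))


def compose(ops) -> BlochOperator:
    """Compose a sequence of affine operators applied in list order.

    ``compose([op1, op2])(M) == op2(op1(M))``.  An empty sequence yields the
    identity operator (by convention, not an error).
    """
    out = identity()
    for op in ops:
        out = out.then(op)
    return out


def rotation(alpha_deg: float) -> BlochOperator:
    """RF nutation about the x-axis by ``alpha_deg`` degrees.

    R_alpha = [[1, 0, 0], [0, cos a, sin a], [0, -sin a, cos a]].
    """
    if not math.isfinite(alpha_deg):
        raise ValueError(f"non-finite flip angle {alpha_deg}")
    a = math.radians(alpha_deg)
    c, s = math.cos(a), math.sin(a)
    return BlochOperator(np.array([[1.0, 0.0, 0.0], [0.0, c, s], [0.0, -s, c]]))


def precession(t_ms: float, delta_f_hz: float) -> BlochOperator:
    """Free precession about z during ``t_ms`` at off-resonance ``delta_f_hz``.

    The transverse plane rotates by theta = 2*pi*delta_f*t with the
    convention mx' = cos(theta) mx + sin(theta) my.
    """
    if t_ms < 0:
        raise ValueError(f"negative precession time {t_ms} ms")
    theta = 2.0 * math.pi * delta_f_hz * t_ms * 1e-3
    c, s = math.cos(theta), math.sin(theta)
    return BlochOperator(np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]]))


def relaxation(t_ms: float, tissue: TissueParams) -> BlochOperator:
    """T1/T2 relaxation during ``t_ms`` toward equilibrium [0, 0, m0].

    C(t) = diag(e^{-t/T2}, e^{-t/T2}, e^{-t/T1}); offset D(t) = (I - C) [0,0,m0].
    """
    if t_ms < 0:
        raise ValueError(f"negative relaxation time {t_ms} ms")
    e2 = math.exp(-t_ms / tissue.t2)
    e1 = math.exp(-t_ms / tissue.t1)
    mat = np.diag([e2, e2, e1])
    off = np.array([0.0, 0.0, tissue.m0 * (1.0 - e1)])
    return BlochOperator(mat, off)


# Convenience functional forms -------------------------------------------------

def rotate(alpha_deg: float, state: MagnetizationState) -> MagnetizationState:
    return rotation(alpha_deg)(state)


def precess(t_ms: float, delta_f_hz: float, state: MagnetizationState) -> MagnetizationState:
    return precession(t_ms, delta_f_hz)(state)


def relax(t_ms: float, tissue: TissueParams, state: MagnetizationState) -> MagnetizationState:
    return relaxation(t_ms, tissue)(state)
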