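"""Configurable 2-D model potentials for the toy dynamics engine.

The double-well potential stands in for a protein conformational landscape
with two metastable basins ("active" and "inactive", e.g. closed and open
catalytic-loop conformations).  Along the axis joining the two declared
minima the energy is a tilted quartic,

    U(u) = 16 b u^2 (1 - u)^2 + (d_a - d_b) u^2 (3 - 2u),

where u is the fractional position between the minima, ``b`` is the barrier
height (kT) above the first minimum for the untilted well, and ``d_a, d_b``
are the declared basin depths (kT); the smoothstep tilt has zero slope at
u = 0 and u = 1, so the declared minima are exact stationary points and
U(m1) - U(m0) = d_a - d_b.  Transverse displacement v is confined
harmonically with stiffness ``stiffness`` (kT per feature-unit^2), and an
optional bilinear coupling c * u (1 - u) * v skews the saddle region without
moving the minima.  Energies are in kT, coordinates in feature units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = ["PotentialSpec", "evaluate_potential"]

_KINDS = ("harmonic", "double_well_2d")


@dataclass(frozen=True)
class PotentialSpec:
    """Declarative description of a 2-D model potential.

    Parameters
    ----------
    kind : {"harmonic", "double_well_2d"}
    minima : sequence of 2-D points (feature units)
        One point for ``harmonic``, exactly two for ``double_well_2d``.
    depths : sequence of float, kT
        Basin depths, one per minimum; only the difference matters for the
        double well (the first minimum is the energy zero).
    barrier_scale : float, kT
        Barrier height of the untilted double well above its minima.
    coupling : float
        Bilinear saddle-region coupling weight.
    stiffness : float, kT / feature-unit^2
        Transverse stiffness (double well) or isotropic curvature (harmonic).
    """

    kind: str
    minima: tuple = ((0.0, 0.0),)
    depths: tuple = (1.0,)
    barrier_scale: float = 2.5
    coupling: float = 0.0
    stiffness: float = 10.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(f"unknown potential kind {self.kind!r}; valid: {_KINDS}")
        minima = tuple(tuple(float(x) for x in m) for m in self.minima)
        depths = tuple(float(d) for d in self.depths)
        object.__setattr__(self, "minima", minima)
        object.__setattr__(self, "depths", depths)
        if len(minima) < 1:
            raise ConfigurationError("at least one minimum is required")
        if any(len(m) != 2 for m in minima):
            raise ConfigurationError("minima must be 2-D points")
        if len(depths) != len(minima):
            raise ConfigurationError("one depth per minimum is required")
        if any(d <= 0 for d in depths):
            raise ConfigurationError("depths must be positive")
        if self.kind == "double_well_2d":
            if len(minima) != 2:
                raise ConfigurationError("double_well_2d requires exactly two minima")
            if np.allclose(minima[0], minima[1]):
                raise ConfigurationError("double-well minima must be distinct")
        if self.kind == "harmonic" and len(minima) != 1:
            raise ConfigurationError("harmonic requires exactly one minimum")
        if self.stiffness <= 0:
            raise ConfigurationError("stiffness must be positive")
        if self.barrier_scale < 0:
            raise ConfigurationError("barrier_scale must be non-negative")


@dataclass(frozen=True)
class _DoubleWellParams:
    """Precomputed geometry for fast per-step evaluation."""

    m0x: float
    m0y: float
    ex: float
    ey: float  # unit vector m0 -> m1
    length: float
    h: float  # quartic scale, 16 * barrier_scale
    delta: float  # tilt, d_a - d_b
    kt: float
    c: float

    def energy_grad(self, x: float, y: float) -> tuple[float, float, float]:
        dx = x - self.m0x
        dy = y - self.m0y
        u = (dx * self.ex + dy * self.ey) / self.length
        v = -dx * self.ey + dy * self.ex
        omu = 1.0 - u
        e = (
            self.h * u * u * omu * omu
            + self.delta * u * u * (3.0 - 2.0 * u)
            + 0.5 * self.kt * v * v
            + self.c * u * omu * v
        )
        du = (
            self.h * (2.0 * u - 6.0 * u * u + 4.0 * u * u * u)
            + 6.0 * self.delta * (u - u * u)
            + self.c * (1.0 - 2.0 * u) * v
        )
        dv = self.kt * v + self.c * u * omu
        s = du / self.length
        return e, s * self.ex - dv * self.ey, s * self.ey + dv * self.ex


def _dw_params(spec: PotentialSpec) -> _DoubleWellParams:
    m0 = np.asarray(spec.minima[0], float)
    m1 = np.asarray(spec.minima[1], float)
    d = m1 - m0
    length = float(np.linalg.norm(d))
    e = d / length
    return _DoubleWellParams(
        m0x=float(m0[0]),
        m0y=float(m0[1]),
        ex=float(e[0]),
        ey=float(e[1]),
        length=length,
        h=16.0 * spec.barrier_scale,
        delta=spec.depths[0] - spec.depths[1],
        kt=spec.stiffness,
        c=spec.coupling,
    )


def evaluate_potential(spec: PotentialSpec, point) -> tuple[np.ndarray, np.ndarray]:
    """Energy (kT) and analytic gradient at one or many 2-D points.

    Parameters
    ----------
    spec : PotentialSpec
    point : array-like, shape (2,) or (n, 2)

    Returns
    -------
    energy : float or ndarray (n,)
    gradient : ndarray (2,) or (n, 2)
    """
    p = np.asarray(point, dtype=float)
    scalar = p.ndim == 1
    p = np.atleast_2d(p)
    if p.shape[1] != 2:
        raise ConfigurationError("points must be 2-D")
    if not np.all(np.isfinite(p)):
        raise ConfigurationError("points must be finite")

    if spec.kind == "harmonic":
        d = p - np.asarray(spec.minima[0], float)
        energy = 0.5 * spec.stiffness * np.sum(d * d, axis=1)
        grad = spec.stiffness * d
    else:
        pw = _dw_params(spec)
        dx = p[:, 0] - pw.m0x
        dy = p[:, 1] - pw.m0y
        u = (dx * pw.ex + dy * pw.ey) / pw.length
        v = -dx * pw.ey + dy * pw.ex
        omu = 1.0 - u
        energy = (
            pw.h * u**2 * omu**2
            + pw.delta * u**2 * (3.0 - 2.0 * u)
            + 0.5 * pw.kt * v**2
            + pw.c * u * omu * v
        )
        du = (
            pw.h * (2.0 * u - 6.0 * u**2 + 4.0 * u**3)
            + 6.0 * pw.delta * (u - u**2)
            + pw.c * (1.0 - 2.0 * u) * v
        )
        dv = pw.kt * v + pw.c * u * omu
        s = du / pw.length
        grad = np.column_stack([s * pw.ex - dv * pw.ey, s * pw.ey + dv * pw.ex])

    if scalar:
        return float(energy[0]), grad[0]
    return energy, grad
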