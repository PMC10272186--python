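"""Overdamped Langevin (Brownian) dynamics with steering and restraints.

This module is a desk-scale stand-in for a molecular dynamics engine.  It
integrates the Euler--Maruyama discretisation of overdamped Langevin
dynamics on the 2-D model potentials of :mod:`allostate.potentials`,

    x_{t+1} = x_t - (dt / gamma) * grad U(x_t) + sqrt(2 kT dt / gamma) * xi_t,

whose stationary law is the Boltzmann distribution exp(-U / kT) / Z.  Two
kinds of bias mirror a steered-MD setup: a time-dependent harmonic steering
restraint whose force constant ramps up linearly before its centre is pulled
from a start to a target value (the pulling stage of a steered simulation),
and stationary flat-bottom restraints that are zero inside a window and
half-harmonic outside it (as used to keep a weakly bound ligand posed).

Energies are in kT, time in integrator steps; no physical unit conversion
is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, IntegrationError
from .potentials import PotentialSpec, _dw_params
from .trajectories import FeatureTrajectory

__all__ = [
    "LangevinParams",
    "SteeringSchedule",
    "FlatBottomRestraint",
    "restraint_energy",
    "simulate",
    "trajectory_seed",
]


@dataclass(frozen=True)
class LangevinParams:
    """Integrator parameters: dt, temperature (kT units), friction, length."""

    dt: float
    temperature: float
    friction: float
    n_steps: int
    save_stride: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.friction <= 0:
            raise ConfigurationError("friction must be positive")
        if self.temperature < 0:
            raise ConfigurationError("temperature must be non-negative")
        if self.save_stride < 1:
            raise ConfigurationError("save_stride must be >= 1")
        if self.n_steps < 1:
            raise ConfigurationError("n_steps must be >= 1")


@dataclass(frozen=True)
class SteeringSchedule:
    """Time-dependent harmonic steering restraint on one feature.

    The force constant rises linearly 0 -> k over ``ramp_steps`` while the
    restraint centre is held at ``start_value`` (the force-application stage);
    the centre then moves linearly from ``start_value`` to ``target_value``,
    reaching it at ``total_steps``, and is held there afterwards.
    """

    cv_index: int
    ramp_steps: int
    k: float
    start_value: float
    target_value: float
    total_steps: int

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ConfigurationError("steering force constant must be >= 0")
        if self.ramp_steps > self.total_steps:
            raise ConfigurationError("ramp_steps must not exceed total_steps")
        if self.ramp_steps < 0:
            raise ConfigurationError("ramp_steps must be >= 0")
        if self.cv_index not in (0, 1):
            raise ConfigurationError("cv_index must be 0 or 1 for 2-D features")

    def at(self, step: int) -> tuple[float, float]:
        """(force constant, centre) applied during integrator step ``step``."""
        if self.ramp_steps > 0 and step < self.ramp_steps:
            return self.k * (step + 1) / self.ramp_steps, self.start_value
        pull = self.total_steps - self.ramp_steps
        if pull > 0 and step < self.total_steps:
            frac = (step - self.ramp_steps + 1) / pull
            return self.k, self.start_value + frac * (self.target_value - self.start_value)
        return self.k, self.target_value


@dataclass(frozen=True)
class FlatBottomRestraint:
    """Zero energy inside [lower, upper]; half-harmonic k * excess^2 / 2 outside."""

    cv_index: int
    lower: float
    upper: float
    k: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ConfigurationError("flat-bottom restraint requires lower <= upper")
        if self.k < 0:
            raise ConfigurationError("restraint force constant must be >= 0")


def restraint_energy(restraint: FlatBottomRestraint, value: float) -> float:
    """Flat-bottom restraint energy (kT) at a feature value."""
    if value > restraint.upper:
        d = value - restraint.upper
    elif value < restraint.lower:
        d = value - restraint.lower
    else:
        return 0.0
    return 0.5 * restraint.k * d * d


def _restraint_force(restraint: FlatBottomRestraint, value: float) -> float:
    """dE/dvalue of the flat-bottom restraint."""
    if value > restraint.upper:
        return restraint.k * (value - restraint.upper)
    if value < restraint.lower:
        return restraint.k * (value - restraint.lower)
    return 0.0


def trajectory_seed(run_seed: int, trajectory_index: int) -> int:
    """Named per-trajectory seed, reproducible under parallel launch.

    Derived from (run seed, trajectory index) through a seed sequence so the
    set of streams is independent of launch order; kept below 2**31.
    """
    ss = np.random.SeedSequence([int(run_seed), int(trajectory_index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


# overflow in a diverging trajectory is detected explicitly at save points
@np.errstate(over="ignore", invalid="ignore")
def simulate(
    spec: PotentialSpec,
    params: LangevinParams,
    steering: SteeringSchedule | None = None,
    restraints: tuple[FlatBottomRestraint, ...] = (),
    x0=None,
    label: str = "",
) -> FeatureTrajectory:
    """Integrate one trajectory; returns ``n_steps // save_stride`` frames.

    The state after every ``save_stride``-th step is saved.  ``x0`` defaults
    to the first declared minimum of the potential.  Identical inputs and
    seed give a bit-identical trajectory.
    """
    if x0 is None:
        x0 = spec.minima[0]
    x = float(x0[0])
    y = float(x0[1])
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ConfigurationError("initial position must be finite")

    dt = params.dt
    inv_gamma = 1.0 / params.friction
    amp = math.sqrt(2.0 * params.temperature * dt * inv_gamma)
    n_steps = params.n_steps
    stride = params.save_stride

    rng = np.random.default_rng(params.seed)
    noise = rng.standard_normal((n_steps, 2)) if amp > 0 else None

    harmonic = spec.kind == "harmonic"
    if harmonic:
        mx, my = spec.minima[0]
        kh = spec.stiffness
    else:
        pw = _dw_params(spec)

    n_frames = n_steps // stride
    out = np.empty((n_frames, 2), dtype=float)
    frame = 0

    try:
        for t in range(n_steps):
            if harmonic:
                gx = kh * (x - mx)
                gy = kh * (y - my)
            else:
                _, gx, gy = pw.energy_grad(x, y)
            if steering is not None:
                k_t, centre = steering.at(t)
                if steering.cv_index == 0:
                    gx += k_t * (x - centre)
                else:
                    gy += k_t * (y - centre)
            for r in restraints:
                f = _restraint_force(r, x if r.cv_index == 0 else y)
                if r.cv_index == 0:
                    gx += f
                else:
                    gy += f
            x -= dt * inv_gamma * gx
            y -= dt * inv_gamma * gy
            if noise is not None:
                x += amp * noise[t, 0]
                y += amp * noise[t, 1]
            if (t + 1) % stride == 0:
                if not (math.isfinite(x) and math.isfinite(y)):
                    raise IntegrationError(
                        f"non-finite coordinates at integrator step {t + 1}"
                    )
                out[frame, 0] = x
                out[frame, 1] = y
                frame += 1
    except OverflowError as exc:  # pragma: no cover - defensive
        raise IntegrationError(f"integration blew up at step {t + 1}") from exc

    meta = {
        "seed": params.seed,
        "potential": {
            "kind": spec.kind,
            "minima": [list(m) for m in spec.minima],
            "depths": list(spec.depths),
            "barrier_scale": spec.barrier_scale,
            "coupling": spec.coupling,
            "stiffness": spec.stiffness,
        },
        "langevin": {
            "dt": dt,
            "temperature": params.temperature,
            "friction": params.friction,
            "n_steps": n_steps,
            "save_stride": stride,
        },
        "steering": None
        if steering is None
        else {
            "cv_index": steering.cv_index,
            "ramp_steps": steering.ramp_steps,
            "k": steering.k,
            "start_value": steering.start_value,
            "target_value": steering.target_value,
            "total_steps": steering.total_steps,
        },
        "restraints": [
            {"cv_index": r.cv_index, "lower": r.lower, "upper": r.upper, "k": r.k}
            for r in restraints
        ],
        "x0": [float(x0[0]), float(x0[1])],
    }
    return FeatureTrajectory(
        out, ["feature_1", "feature_2"], frame_interval=float(stride), label=label, metadata=meta
    )
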