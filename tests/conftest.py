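"""Shared fixtures: small toy landscapes and a pre-simulated seeded swarm."""

import numpy as np
import pytest

from allostate import (
    LangevinParams,
    PotentialSpec,
    SteeringSchedule,
    extract_seeds,
    simulate,
    trajectory_seed,
)


@pytest.fixture(scope="session")
def double_well() -> PotentialSpec:
    """Symmetric two-basin landscape used throughout the suite."""
    return PotentialSpec(
        "double_well_2d",
        minima=[(0.5, 0.3), (2.5, 0.9)],
        depths=(3.5, 3.5),
        barrier_scale=2.2,
    )


@pytest.fixture(scope="session")
def tilted_well() -> PotentialSpec:
    """Asymmetric double well: second basin 2 kT above the first."""
    return PotentialSpec(
        "double_well_2d",
        minima=[(0.0, 0.0), (3.0, 0.0)],
        depths=(4.0, 2.0),
        barrier_scale=2.2,
    )


@pytest.fixture(scope="session")
def small_swarm(double_well):
    """A modest seeded swarm on the symmetric double well (30 trajectories).

    Steer across the barrier, pick 15 seeds per direction, run 500-frame
    equilibrium trajectories from each seed.  Session-scoped: several MSM
    and comparison tests reuse it.
    """
    lv = dict(dt=0.008, temperature=1.0, friction=1.0)
    swarm = []
    idx = 0
    for direction, (a, b) in enumerate(
        [(double_well.minima[0], double_well.minima[1]),
         (double_well.minima[1], double_well.minima[0])]
    ):
        sched = SteeringSchedule(
            cv_index=0, ramp_steps=200, k=25.0,
            start_value=a[0], target_value=b[0], total_steps=4000,
        )
        steer = simulate(
            double_well,
            LangevinParams(**lv, n_steps=4000, save_stride=1,
                           seed=trajectory_seed(90, direction)),
            sched, x0=a,
        )
        seeds = extract_seeds(steer, "feature_1", 15)
        for f in seeds.frames:
            swarm.append(
                simulate(
                    double_well,
                    LangevinParams(**lv, n_steps=5000, save_stride=10,
                                   seed=trajectory_seed(91, idx)),
                    x0=steer.values[f], label=f"swarm_{idx}",
                )
            )
            idx += 1
    return swarm


def sample_markov_chain(T, n_steps, rng, s0=0):
    """Exact sampling from a discrete-time Markov chain (test oracle input)."""
    T = np.asarray(T, float)
    cum = np.cumsum(T, axis=1)
    states = np.empty(n_steps, dtype=np.int64)
    s = s0
    u = rng.random(n_steps)
    for t in range(n_steps):
        states[t] = s
        s = int(np.searchsorted(cum[s], u[t]))
    return states


@pytest.fixture(scope="session")
def chain_sampler():
    return sample_markov_chain
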