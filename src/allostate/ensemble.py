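"""MSM-weighted conformational analysis.

The stationary distribution lives on microstates; to analyse conformations
one maps it back to frames.  A frame assigned to microstate i receives
weight p_i / n_i where n_i is the number of frames in that microstate, so
microstate-aggregated frame weights reproduce the microstate probabilities
exactly.  Frames may then be resampled with replacement according to these
weights (e.g. 10,000 draws) to build equilibrium-weighted conformational
ensembles, or restricted to one macrostate by using its metastable
distribution instead of the full stationary vector.  A periodic
side-chain-rotamer histogram classifies chi1 dihedrals into "up"
(around -60 deg) and "down" (around -180 deg) states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DefinitionError
from .msm import DiscreteTrajectory, MacrostateDefinition, MSMResults

__all__ = [
    "FrameWeights",
    "frame_weights",
    "sample_frames",
    "metastable_distributions",
    "weighted_rotamer_histogram",
    "ROTAMER_WINDOWS",
]

# chi1 windows (degrees) anchored at the reported "up" (-60) and "down"
# (-180) readings; configurable via the `windows` argument below.
ROTAMER_WINDOWS = {
    "up": ((-120.0, 0.0),),
    "down": ((-180.0, -120.0), (120.0, 180.0)),
}


@dataclass
class FrameWeights:
    """Per-frame equilibrium weights across all trajectories of a system.

    ``weights`` is a list of arrays, one per trajectory, summing to one
    over all frames; frames of the same microstate share a weight.
    """

    weights: list[np.ndarray]
    normalization: float  # probability mass retained before renormalising

    @property
    def flat(self) -> np.ndarray:
        return np.concatenate(self.weights)

    @property
    def n_frames(self) -> int:
        return sum(w.size for w in self.weights)


def frame_weights(dtrajs: list[DiscreteTrajectory], probabilities: np.ndarray) -> FrameWeights:
    """Map microstate probabilities to per-frame weights.

    Each frame in microstate i gets weight p_i / n_i.  Probability mass on
    microstates with zero frames cannot be represented: it is dropped and
    the remainder renormalised, with a warning reporting the lost mass.
    """
    p = np.asarray(probabilities, float)
    if np.any(p < 0):
        raise DefinitionError("probabilities must be non-negative")
    states = [np.asarray(d.states if isinstance(d, DiscreteTrajectory) else d) for d in dtrajs]
    counts = np.zeros(p.size, dtype=np.int64)
    for s in states:
        counts += np.bincount(s, minlength=p.size)
    missing = (p > 0) & (counts == 0)
    lost = float(p[missing].sum())
    if lost > 0:
        warnings.warn(
            f"{lost:.4g} probability mass on microstates with no frames; "
            "dropped and renormalised",
            stacklevel=2,
        )
    per_state = np.zeros(p.size)
    ok = counts > 0
    per_state[ok] = p[ok] / counts[ok]
    weights = [per_state[s] for s in states]
    total = sum(w.sum() for w in weights)
    if total <= 0:
        raise DefinitionError("no probability mass on any visited microstate")
    weights = [w / total for w in weights]
    return FrameWeights(weights, normalization=1.0 - lost)


def sample_frames(weights: FrameWeights, n: int, seed: int = 0) -> np.ndarray:
    """Draw ``n`` frame indices with replacement, proportional to weight.

    Returns global frame indices into the concatenation of the system's
    trajectories; deterministic for a fixed seed.
    """
    if n < 1:
        raise DefinitionError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.choice(weights.n_frames, size=n, replace=True, p=weights.flat)


def metastable_distributions(
    results: MSMResults, macro: MacrostateDefinition
) -> dict[str, np.ndarray]:
    """Per-macrostate probability vectors over microstates.

    Each macrostate's distribution is its (fuzzy) PCCA membership weighted
    by the stationary probability and renormalised:
    p^A_i = chi_iA * pi_i / sum_j chi_jA * pi_j.  Vectors cover all
    microstates, zero off the active set.
    """
    if macro.memberships is None or macro.active_set is None:
        raise DefinitionError("macrostate definition carries no PCCA memberships")
    pi_a = results.stationary_distribution[macro.active_set]
    out: dict[str, np.ndarray] = {}
    names = macro.label_names
    # map membership columns to labels via the crisp assignment
    crisp = np.argmax(macro.memberships, axis=1)
    for name in names:
        cols = np.unique(crisp[macro.labels[macro.active_set] == name])
        chi = macro.memberships[:, cols].sum(axis=1)
        vec = np.zeros(results.n_states)
        mass = chi * pi_a
        if mass.sum() <= 0:
            raise DefinitionError(f"macrostate {name!r} has zero stationary mass")
        vec[macro.active_set] = mass / mass.sum()
        out[name] = vec
    return out


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Map angles to (-180, 180]."""
    a = np.asarray(a, float)
    wrapped = ((a + 180.0) % 360.0) - 180.0
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    return wrapped


def weighted_rotamer_histogram(
    angles: np.ndarray,
    weights: np.ndarray | None = None,
    bins: int = 72,
    windows: dict | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Weighted periodic histogram of a dihedral series plus rotamer fractions.

    Parameters
    ----------
    angles : array of degrees in (-180, 180] (wrapped if outside).
    weights : optional per-angle weights (normalised internally).
    bins : number of periodic bins over (-180, 180].
    windows : rotamer class windows; default anchors "up" around -60 deg
        and "down" around -180 deg, everything else is "other".

    Returns
    -------
    histogram : DataFrame with bin centres and weighted density.
    fractions : dict of rotamer class -> weighted fraction.
    """
    a = _wrap_angle(angles)
    if weights is None:
        w = np.full(a.size, 1.0 / a.size)
    else:
        w = np.asarray(weights, float)
        if w.size != a.size:
            raise DefinitionError("weights must match the angle series")
        w = w / w.sum()
    edges = np.linspace(-180.0, 180.0, bins + 1)
    hist, _ = np.histogram(a, bins=edges, weights=w)
    centres = 0.5 * (edges[:-1] + edges[1:])
    df = pd.DataFrame({"angle": centres, "density": hist / (edges[1] - edges[0])})

    windows = ROTAMER_WINDOWS if windows is None else windows
    fractions: dict[str, float] = {}
    assigned = np.zeros(a.size, dtype=bool)
    for name, spans in windows.items():
        mask = np.zeros(a.size, dtype=bool)
        for lo, hi in spans:
            if hi == 180.0:
                mask |= (a >= lo) & (a <= hi)
            else:
                mask |= (a >= lo) & (a < hi)
        fractions[name] = float(w[mask].sum())
        assigned |= mask
    fractions["other"] = float(w[~assigned].sum())
    return df, fractions
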