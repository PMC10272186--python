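"""Seed-frame extraction from steering trajectories.

A steered trajectory drags a reaction coordinate across its full range;
short equilibrium "swarm" simulations are then launched from snapshots that
evenly sample that range.  "Evenly" is read as even in coordinate value:
targets are linearly spaced over the observed [min, max] of the coordinate,
and for each target the nearest frame is selected (earliest frame on ties).
Duplicate frame picks are collapsed and the shortfall reported rather than
silently padded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateRangeError
from .trajectories import FeatureTrajectory

__all__ = ["SeedSet", "extract_seeds"]


@dataclass
class SeedSet:
    """Frames selected from one steering trajectory to launch a swarm."""

    source: str
    frames: np.ndarray  # per-target frame index, ordered by target
    targets: np.ndarray  # requested coordinate values
    realized: np.ndarray  # coordinate value of each chosen frame
    n_collapsed: int  # duplicate picks removed in unique_frames

    @property
    def unique_frames(self) -> np.ndarray:
        """De-duplicated frame indices, strictly increasing."""
        return np.unique(self.frames)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": self.frames, "target": self.targets, "realized": self.realized}
        )

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")


def extract_seeds(traj: FeatureTrajectory, coord: str, n_seeds: int) -> SeedSet:
    """Select ``n_seeds`` frames evenly sampling the observed coordinate range.

    Parameters
    ----------
    traj : FeatureTrajectory
        The steering trajectory.
    coord : str
        Name of the feature column used as the reaction coordinate.
    n_seeds : int
        Number of targets; must not exceed the number of frames.

    Returns
    -------
    SeedSet
        Per-target frame picks; ``unique_frames`` gives the de-duplicated
        launch set and ``n_collapsed`` how many targets shared a frame.
    """
    if n_seeds < 1:
        raise ConfigurationError("n_seeds must be >= 1")
    if traj.n_frames < n_seeds:
        raise ConfigurationError(
            f"trajectory has {traj.n_frames} frames, fewer than n_seeds={n_seeds}"
        )
    values = traj.column(coord)
    vmin, vmax = float(values.min()), float(values.max())
    if vmax - vmin <= 1e-12:
        raise DegenerateRangeError(
            f"coordinate {coord!r} is constant ({vmin}); cannot space seeds"
        )
    targets = np.linspace(vmin, vmax, n_seeds)
    # argmin returns the first (earliest-frame) index on ties
    frames = np.array([int(np.argmin(np.abs(values - t))) for t in targets])
    realized = values[frames]
    n_collapsed = len(frames) - len(np.unique(frames))
    return SeedSet(traj.label, frames, targets, realized, n_collapsed)
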