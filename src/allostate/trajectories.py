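"""Feature-space trajectory container and its plain-text round trip.

A :class:`FeatureTrajectory` is the common currency of the package: a
time-ordered matrix of frames in a low-dimensional feature space (for a
phosphatase this would be e.g. WPD-loop and P-loop backbone RMSD to the
closed crystal conformation, in Angstrom).  Trajectories are written as
delimited text with a ``frame`` index column and one column per feature,
optionally with a JSON sidecar recording provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FeatureMismatchError

__all__ = ["FeatureTrajectory"]


@dataclass
class FeatureTrajectory:
    """Time-ordered frames in feature space.

    Parameters
    ----------
    values : ndarray, shape (n_frames, n_features)
        Feature values, one row per frame.  Must be finite.
    feature_names : list of str
        One name per column.
    frame_interval : float
        Time between saved frames, in the trajectory's own time unit
        (integrator steps for toy dynamics, ps for real data).
    label : str
        System label (e.g. ``"reference"``, ``"ligand-1"``).
    """

    values: np.ndarray
    feature_names: list[str]
    frame_interval: float = 1.0
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FeatureMismatchError("values must be a 2-D (frames x features) array")
        if len(self.feature_names) != self.values.shape[1]:
            raise FeatureMismatchError(
                f"{len(self.feature_names)} feature names for "
                f"{self.values.shape[1]} columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise FeatureMismatchError("feature values must be finite (no missing values)")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.feature_names.index(name)
        except ValueError:
            raise FeatureMismatchError(
                f"no feature named {name!r}; have {self.feature_names}"
            ) from None
        return self.values[:, j]

    def slice(self, start: int | None = None, stop: int | None = None) -> "FeatureTrajectory":
        return FeatureTrajectory(
            self.values[start:stop].copy(),
            list(self.feature_names),
            self.frame_interval,
            self.label,
            dict(self.metadata),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "frame", np.arange(self.n_frames))
        return df

    def write(self, path: str | Path, sidecar: bool = True) -> None:
        """Write as delimited text; optionally a ``<path>.meta.json`` sidecar."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")
        if sidecar:
            meta = {
                "label": self.label,
                "frame_interval": self.frame_interval,
                "feature_names": self.feature_names,
                **self.metadata,
            }
            Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def read(cls, path: str | Path) -> "FeatureTrajectory":
        path = Path(path)
        df = pd.read_csv(path)
        names = [c for c in df.columns if c != "frame"]
        meta_path = Path(str(path) + ".meta.json")
        label, interval, metadata = "", 1.0, {}
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            label = meta.pop("label", "")
            interval = float(meta.pop("frame_interval", 1.0))
            meta.pop("feature_names", None)
            metadata = meta
        return cls(df[names].to_numpy(float), names, interval, label, metadata)
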