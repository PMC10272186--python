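"""Multi-system comparison: shared microstates, transferred macrostates,
bootstrapped active-state probability distributions and the effect call.

The protocol compares the probability that a protein is in its
catalytically active conformational macrostate with and without a bound
ligand.  All systems are discretised with a single k-means model fitted on
the pooled feature data so that microstates mean the same thing everywhere;
the active/inactive partition comes from PCCA of the reference system and
is transferred unchanged to every other system, with microstates the
reference never visited assigned to the inactive macrostate.  Microstates a
given system never visits carry stationary probability zero.  Uncertainty
is quantified by bootstrapping: trajectories are resampled with
replacement, the transition model re-estimated with the fixed microstate
and macrostate definitions, and the active-state probability recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DefinitionError, EstimationError, FeatureMismatchError
from .msm import (
    ClusterModel,
    DiscreteTrajectory,
    MacrostateDefinition,
    MarkovStateModel,
    MSMResults,
    assign,
    fit_kmeans,
)
from .trajectories import FeatureTrajectory

__all__ = [
    "SystemEnsemble",
    "ActiveStateDistribution",
    "EffectCall",
    "pool_and_cluster",
    "active_probability",
    "transfer_macrostates",
    "bootstrap_distribution",
    "classify_effect",
]


@dataclass
class SystemEnsemble:
    """One system's seeded swarm: a label and its feature trajectories."""

    label: str
    trajectories: list[FeatureTrajectory]

    def __post_init__(self) -> None:
        if len(self.trajectories) < 2:
            raise FeatureMismatchError("a system ensemble needs >= 2 trajectories")
        names = list(self.trajectories[0].feature_names)
        for t in self.trajectories[1:]:
            if list(t.feature_names) != names:
                raise FeatureMismatchError("all trajectories of a system must share features")

    @property
    def feature_names(self) -> list[str]:
        return list(self.trajectories[0].feature_names)

    def discretize(self, model: ClusterModel) -> list[DiscreteTrajectory]:
        return [assign(t, model) for t in self.trajectories]


@dataclass
class ActiveStateDistribution:
    """Bootstrap sample of active-state probabilities for one system."""

    label: str
    values: np.ndarray  # (n_iterations,), each in [0, 1]
    n_iterations: int
    n_trajectories: int
    seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.size != self.n_iterations:
            raise DefinitionError("sample size must equal n_iterations")
        if np.any((self.values < 0) | (self.values > 1)):
            raise DefinitionError("active-state probabilities must lie in [0, 1]")

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"iteration": np.arange(self.n_iterations), "probability": self.values}
        )

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")


def pool_and_cluster(systems: list[SystemEnsemble], k: int, seed: int = 0) -> ClusterModel:
    """Fit one k-means microstate model on all systems' pooled frames.

    The returned model is used unchanged for every system, so microstate
    indices are comparable across systems (some microstates may then be
    unpopulated for a given system).
    """
    names = systems[0].feature_names
    for s in systems[1:]:
        if s.feature_names != names:
            raise FeatureMismatchError(
                f"system {s.label!r} features {s.feature_names} do not match {names}"
            )
    pooled = [t for s in systems for t in s.trajectories]
    return fit_kmeans(pooled, k, seed)


def active_probability(model: MSMResults, macro: MacrostateDefinition) -> float:
    """Sum of stationary probabilities over microstates labelled active.

    The stationary distribution is defined over all microstates with zeros
    where the system never visits, so unvisited active microstates simply
    contribute nothing.  Every microstate must be labelled.
    """
    pi = model.stationary_distribution
    if macro.n_states != pi.size:
        raise DefinitionError(
            f"macrostate definition covers {macro.n_states} microstates, model has {pi.size}"
        )
    unlabelled = np.flatnonzero(macro.labels == "")
    if unlabelled.size:
        raise DefinitionError(f"unlabelled microstates: {unlabelled.tolist()[:10]}")
    return float(pi[macro.active_states].sum())


def transfer_macrostates(
    reference_macro: MacrostateDefinition, n_states: int | None = None
) -> MacrostateDefinition:
    """Extend the reference PCCA labelling to all microstates.

    Microstates the reference system did not sample (unlabelled) are
    assigned to the inactive macrostate, so a system that populates them
    can only lower its active-state probability.
    """
    if n_states is None:
        n_states = reference_macro.n_states
    if n_states < reference_macro.n_states:
        raise DefinitionError("cannot shrink a macrostate definition")
    labels = np.array([""] * n_states, dtype=object)
    labels[: reference_macro.n_states] = reference_macro.labels
    labels[labels == ""] = "inactive"
    return MacrostateDefinition(labels, reference_macro.source)


def bootstrap_distribution(
    system: SystemEnsemble | list[DiscreteTrajectory],
    cluster_model: ClusterModel | None,
    macro: MacrostateDefinition,
    lag: int,
    n_iter: int = 100,
    n_traj: int = 200,
    seed: int = 0,
    reversible: bool = True,
    label: str | None = None,
) -> ActiveStateDistribution:
    """Bootstrap the active-state probability by resampling trajectories.

    Each iteration draws ``n_traj`` trajectories with replacement,
    re-estimates the transition model at the fixed lag with the fixed
    microstate definition, and records the active-state probability under
    the fixed macrostate definition.  Deterministic for a fixed seed.  An
    iteration whose resample has no connected counts records probability 0
    with a warning.
    """
    if isinstance(system, SystemEnsemble):
        dtrajs = system.discretize(cluster_model)
        label = system.label if label is None else label
    else:
        dtrajs = system
        label = label or ""
    if n_iter < 1 or n_traj < 1:
        raise DefinitionError("n_iter and n_traj must be >= 1")
    n_states = macro.n_states
    values = np.empty(n_iter)
    for it in range(n_iter):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), it]))
        pick = rng.integers(0, len(dtrajs), size=n_traj)
        sample = [dtrajs[i] for i in pick]
        try:
            res = MarkovStateModel(sample, lag, n_states, reversible).fit()
            values[it] = active_probability(res, macro)
        except EstimationError as exc:
            warnings.warn(
                f"bootstrap iteration {it} for {label!r}: empty active set ({exc}); "
                "recording probability 0",
                stacklevel=2,
            )
            values[it] = 0.0
    return ActiveStateDistribution(label, values, n_iter, n_traj, seed)


@dataclass
class EffectCall:
    """Classification of a system against the reference distribution."""

    label: str  # inhibitor | no_effect | activator
    system: str
    system_median: float
    reference_median: float
    shift: float  # system_median - reference_median
    overlap_fraction: float  # fraction of system values inside the reference range
    threshold: float

    def __str__(self) -> str:
        return (
            f"{self.system}: {self.label} "
            f"(median {self.system_median:.3f} vs reference {self.reference_median:.3f}, "
            f"shift {self.shift:+.3f}, overlap {self.overlap_fraction:.2f})"
        )


def classify_effect(
    system: ActiveStateDistribution,
    reference: ActiveStateDistribution,
    shift_threshold: float = 0.05,
) -> EffectCall:
    """Call a ligand's effect from the bootstrap distributions.

    ``inhibitor`` if the system median active-state probability lies more
    than ``shift_threshold`` (absolute probability) below the reference
    median, ``activator`` if above, ``no_effect`` otherwise.  The summary
    also reports the fraction of system bootstrap values falling inside the
    reference distribution's [min, max] range, so users can apply other
    decision rules.
    """
    if system.values.size == 0 or reference.values.size == 0:
        raise DefinitionError("both distributions must be non-empty")
    med_s = system.median
    med_r = reference.median
    shift = med_s - med_r
    if shift < -shift_threshold:
        label = "inhibitor"
    elif shift > shift_threshold:
        label = "activator"
    else:
        label = "no_effect"
    lo, hi = reference.values.min(), reference.values.max()
    overlap = float(np.mean((system.values >= lo) & (system.values <= hi)))
    return EffectCall(label, system.label, med_s, med_r, shift, overlap, shift_threshold)
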