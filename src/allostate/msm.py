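"""Markov state model core: clustering, estimation, validation, lumping.

The modelling surface follows the Model/Results pattern: a
:class:`MarkovStateModel` is constructed from discrete trajectories and a
lag time, and :meth:`MarkovStateModel.fit` returns an :class:`MSMResults`
carrying the count matrix, the row-stochastic transition matrix on the
largest strongly connected (active) set, its eigen-decomposition, the
stationary distribution padded with zeros off the active set, implied
timescales, a Chapman--Kolmogorov test and PCCA+ macrostate lumping.

Estimation is reversible maximum likelihood by default (detailed balance
enforced through the standard self-consistent fixed-point iteration);
non-reversible row normalisation of the counts is available with
``reversible=False``.  Counting uses a sliding window: every frame pair
(x_t, x_{t+lag}) of every trajectory contributes one count, and
trajectories are never concatenated across boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from .errors import DefinitionError, EstimationError, FeatureMismatchError
from .trajectories import FeatureTrajectory

__all__ = [
    "ClusterModel",
    "DiscreteTrajectory",
    "fit_kmeans",
    "assign",
    "count_matrix",
    "largest_connected_set",
    "MarkovStateModel",
    "MSMResults",
    "estimate_transition_model",
    "implied_timescales",
    "MacrostateDefinition",
    "pcca",
    "CKResult",
]


# ---------------------------------------------------------------------------
# microstate clustering


@dataclass
class ClusterModel:
    """k-means microstate definition: centres in feature space."""

    centers: np.ndarray  # (k, d)
    feature_names: list[str]
    seed: int = 0

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, float)
        if self.centers.ndim != 2 or self.centers.shape[0] < 1:
            raise EstimationError("a cluster model needs >= 1 centre")
        if not np.all(np.isfinite(self.centers)):
            raise EstimationError("cluster centres must be finite")

    @property
    def n_states(self) -> int:
        return self.centers.shape[0]

    def write(self, path) -> None:
        df = pd.DataFrame(self.centers, columns=self.feature_names)
        df.insert(0, "state", np.arange(self.n_states))
        df.to_csv(path, index=False, float_format="%.10g")


@dataclass
class DiscreteTrajectory:
    """Per-frame microstate index sequence after clustering."""

    states: np.ndarray  # int, values in [0, n_states)
    n_states: int
    label: str = ""
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 1:
            raise EstimationError("a discrete trajectory is a 1-D index sequence")
        if self.states.size and (self.states.min() < 0 or self.states.max() >= self.n_states):
            raise EstimationError("state index out of range [0, n_states)")

    def __len__(self) -> int:
        return self.states.size

    def write(self, path) -> None:
        np.savetxt(path, self.states, fmt="%d")


def _pool(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, FeatureTrajectory):
        return data.values, list(data.feature_names)
    if isinstance(data, np.ndarray):
        return data, [f"feature_{j + 1}" for j in range(data.shape[1])]
    names = list(data[0].feature_names)
    for t in data[1:]:
        if list(t.feature_names) != names:
            raise FeatureMismatchError("pooled trajectories must share feature names")
    return np.vstack([t.values for t in data]), names


def fit_kmeans(data, k: int, seed: int = 0) -> ClusterModel:
    """Fit k-means microstates on pooled feature data.

    Uses k-means++ initialisation and Lloyd iterations (scikit-learn, single
    deterministic initialisation for a fixed seed, up to 500 iterations).
    ``data`` may be an (n, d) array, a FeatureTrajectory or a list of them.
    """
    X, names = _pool(data)
    if np.unique(X, axis=0).shape[0] < k:
        raise EstimationError(f"need at least k={k} distinct rows to place {k} centres")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=1,
        max_iter=500,
        tol=1e-10,
        algorithm="lloyd",
        random_state=seed,
    ).fit(X)
    return ClusterModel(km.cluster_centers_, names, seed)


def assign(traj: FeatureTrajectory, model: ClusterModel) -> DiscreteTrajectory:
    """Nearest-centre assignment; ties broken towards the lowest index."""
    if list(traj.feature_names) != list(model.feature_names):
        raise FeatureMismatchError(
            f"trajectory features {traj.feature_names} do not match "
            f"cluster model features {model.feature_names}"
        )
    # squared distances; argmin returns the first (lowest) index on ties
    d2 = (
        np.sum(traj.values**2, axis=1)[:, None]
        - 2.0 * traj.values @ model.centers.T
        + np.sum(model.centers**2, axis=1)[None, :]
    )
    states = np.argmin(d2, axis=1)
    return DiscreteTrajectory(states, model.n_states, traj.label, traj.frame_interval)


# ---------------------------------------------------------------------------
# counting and estimation


def _state_arrays(dtrajs) -> list[np.ndarray]:
    if isinstance(dtrajs, DiscreteTrajectory):
        dtrajs = [dtrajs]
    out = []
    for d in dtrajs:
        out.append(d.states if isinstance(d, DiscreteTrajectory) else np.asarray(d, np.int64))
    return out


def count_matrix(dtrajs, lag: int, n_states: int | None = None) -> np.ndarray:
    """Sliding-window transition counts at the given lag (frames).

    Every pair (x_t, x_{t+lag}) of every trajectory longer than ``lag``
    adds one count; trajectories are never concatenated.
    """
    if lag < 1:
        raise EstimationError("lag must be >= 1 frame")
    arrays = _state_arrays(dtrajs)
    if n_states is None:
        n_states = max(
            [d.n_states for d in (dtrajs if isinstance(dtrajs, list) else [dtrajs])
             if isinstance(d, DiscreteTrajectory)]
            + [int(a.max()) + 1 for a in arrays if a.size],
            default=0,
        )
    C = np.zeros((n_states, n_states), dtype=float)
    any_counts = False
    for a in arrays:
        if a.size <= lag:
            continue
        np.add.at(C, (a[:-lag], a[lag:]), 1.0)
        any_counts = True
    if not any_counts:
        raise EstimationError(f"all trajectories are shorter than lag={lag}; no counts")
    return C


def largest_connected_set(C: np.ndarray) -> np.ndarray:
    """Largest strongly connected component of the count graph.

    Ties in component size are broken towards the component with more
    counts.  States with no counts at all form singleton components and are
    excluded unless nothing else exists.
    """
    n = C.shape[0]
    n_comp, labels = connected_components(csr_matrix(C > 0), directed=True, connection="strong")
    best, best_key = None, None
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        weight = C[np.ix_(members, members)].sum()
        has_counts = C[members].sum() + C[:, members].sum() > 0
        key = (int(has_counts), members.size, weight)
        if best_key is None or key > best_key:
            best, best_key = members, key
    if best is None or C[np.ix_(best, best)].sum() == 0:
        raise EstimationError("empty active set: no connected transition counts")
    return best


def _reversible_mle(C: np.ndarray, tol: float = 1e-12, maxiter: int = 1_000_000):
    """Reversible MLE via the standard self-consistent fixed-point iteration.

    Iterates x_ij = (C_ij + C_ji) / (c_i / x_i + c_j / x_j) on the symmetric
    unnormalised flux matrix x until the maximum elementwise change of the
    normalised x falls below ``tol``.  Returns (T, pi).
    """
    Csym = C + C.T
    c = C.sum(axis=1)
    x = Csym / Csym.sum()
    mask = Csym > 0
    for _ in range(maxiter):
        xi = x.sum(axis=1)
        denom = c[:, None] / xi[:, None] + c[None, :] / xi[None, :]
        x_new = np.where(mask, Csym / np.where(denom > 0, denom, 1.0), 0.0)
        x_new /= x_new.sum()
        delta = np.max(np.abs(x_new - x))
        x = x_new
        if delta < tol:
            break
    else:  # pragma: no cover
        raise EstimationError("reversible MLE fixed-point iteration did not converge")
    xi = x.sum(axis=1)
    T = x / xi[:, None]
    pi = xi / xi.sum()
    return T, pi


def _eigensystem(T: np.ndarray, pi: np.ndarray, reversible: bool):
    """Eigenvalues (descending) and right eigenvectors of T.

    For reversible T the symmetrised matrix diag(sqrt(pi)) T diag(1/sqrt(pi))
    is diagonalised with a symmetric solver, guaranteeing real spectra.
    """
    if reversible:
        s = np.sqrt(pi)
        S = (s[:, None] * T) / s[None, :]
        S = 0.5 * (S + S.T)
        w, V = np.linalg.eigh(S)
        order = np.argsort(w)[::-1]
        w = w[order]
        psi = V[:, order] / s[:, None]
        # normalise the stationary eigenvector to exactly one
        psi[:, 0] = psi[:, 0] / psi[0, 0]
        return w.astype(float), psi
    w, V = scipy.linalg.eig(T)
    order = np.argsort(-np.abs(w))
    w = w[order]
    V = V[:, order]
    if np.max(np.abs(w.imag)) < 1e-12:
        w = w.real
        V = V.real
    return w, V


def _stationary_from_T(T: np.ndarray) -> np.ndarray:
    w, V = scipy.linalg.eig(T.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(V[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# macrostates (PCCA+)


@dataclass
class MacrostateDefinition:
    """Microstate -> {"active", "inactive"} labelling.

    ``labels`` has one entry per microstate; the empty string marks a
    microstate not labelled yet (e.g. outside the reference active set
    before transfer).
    """

    labels: np.ndarray  # object array of str, length n_states
    source: str = ""
    memberships: np.ndarray | None = None  # (n_active, n_macro) fuzzy PCCA+
    active_set: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)

    @property
    def n_states(self) -> int:
        return self.labels.size

    def states(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    @property
    def active_states(self) -> np.ndarray:
        return self.states("active")

    @property
    def label_names(self) -> list[str]:
        return sorted({str(l) for l in self.labels if l})

    def permuted(self, perm: np.ndarray) -> "MacrostateDefinition":
        """Labelling after relabelling microstate i -> perm[i]."""
        new = np.empty_like(self.labels)
        new[np.asarray(perm)] = self.labels
        return MacrostateDefinition(new, self.source)

    def write(self, path) -> None:
        pd.DataFrame(
            {"state": np.arange(self.n_states), "label": list(self.labels)}
        ).to_csv(path, index=False)


def _inner_simplex_memberships(evec: np.ndarray) -> np.ndarray:
    """PCCA+ memberships from the leading eigenvectors (inner simplex).

    ``evec`` is (n, m) with a constant first column.  Finds m rows spanning
    the membership simplex, maps all rows through the inverse vertex matrix,
    clips tiny negative memberships and renormalises.
    """
    n, m = evec.shape
    X = evec.copy()
    idx = np.zeros(m, dtype=int)
    ortho = X.copy()
    idx[0] = int(np.argmax(np.linalg.norm(ortho, axis=1)))
    ortho = ortho - ortho[idx[0]]
    for j in range(1, m):
        dists = np.linalg.norm(ortho, axis=1)
        idx[j] = int(np.argmax(dists))
        if dists[idx[j]] < 1e-12:
            raise EstimationError(
                "degenerate eigenvector structure: fewer metastable sets than requested"
            )
        direction = ortho[idx[j]] / dists[idx[j]]
        ortho = ortho - np.outer(ortho @ direction, direction)
    A = np.linalg.inv(X[idx])
    chi = X @ A
    chi = np.clip(chi, 0.0, None)
    chi /= chi.sum(axis=1, keepdims=True)
    return chi


def pcca(
    results: "MSMResults",
    n_macro: int = 2,
    microstate_values: np.ndarray | None = None,
    source: str = "reference",
) -> MacrostateDefinition:
    """PCCA+ lumping of the active set into metastable macrostates.

    Memberships are computed from the first ``n_macro`` right eigenvectors
    of the (reversibilised, if necessary) transition matrix; the crisp
    assignment is the argmax membership.  ``microstate_values`` (one value
    per microstate, typically the first-feature coordinate of each cluster
    centre, an RMSD-like quantity) names the macrostates: the macrostate
    whose member microstates have the lower mean value is "active", all
    others "inactive".  Microstates outside the active set are left
    unlabelled (empty string).
    """
    T = results.transition_matrix
    pi_active = results.stationary_distribution[results.active_set]
    pi_active = pi_active / pi_active.sum()
    if not results.reversible:
        # reversibilise for analysis: symmetrised flux, row-normalised
        flux = pi_active[:, None] * T
        flux = 0.5 * (flux + flux.T)
        T = flux / flux.sum(axis=1)[:, None]
    if n_macro < 2 or n_macro > T.shape[0]:
        raise EstimationError(f"n_macro={n_macro} invalid for {T.shape[0]} active states")
    w, psi = _eigensystem(T, pi_active, reversible=True)
    if np.iscomplexobj(w):  # pragma: no cover - reversibilisation precludes this
        raise EstimationError("complex dominant eigenvalues; model not reversible")
    chi = _inner_simplex_memberships(psi[:, :n_macro])
    crisp = np.argmax(chi, axis=1)

    labels = np.array([""] * results.n_states, dtype=object)
    if microstate_values is None:
        for m in range(n_macro):
            labels[results.active_set[crisp == m]] = f"macro_{m}"
    else:
        values = np.asarray(microstate_values, float)
        if values.size != results.n_states:
            raise DefinitionError("microstate_values must have one entry per microstate")
        means = np.array(
            [values[results.active_set[crisp == m]].mean() for m in range(n_macro)]
        )
        active_macro = int(np.argmin(means))
        for m in range(n_macro):
            labels[results.active_set[crisp == m]] = (
                "active" if m == active_macro else "inactive"
            )
    return MacrostateDefinition(labels, source, chi, results.active_set.copy())


# ---------------------------------------------------------------------------
# model / results


@dataclass
class CKResult:
    """Chapman--Kolmogorov test: predicted vs re-estimated self-transitions."""

    lags: np.ndarray  # (steps,) in frames: tau, 2 tau, ...
    labels: list[str]
    predicted: np.ndarray  # (steps, n_macro)
    estimated: np.ndarray  # (steps, n_macro); NaN where data insufficient
    estimated_err: np.ndarray  # binomial-approximation error bars

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s, lag in enumerate(self.lags):
            for j, lab in enumerate(self.labels):
                rows.append(
                    {
                        "lag": int(lag),
                        "macrostate": lab,
                        "predicted": self.predicted[s, j],
                        "estimated": self.estimated[s, j],
                        "estimated_err": self.estimated_err[s, j],
                    }
                )
        return pd.DataFrame(rows)

    def max_deviation_sigmas(self) -> float:
        """Largest |predicted - estimated| in units of the error bar."""
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.abs(self.predicted - self.estimated) / self.estimated_err
        return float(np.nanmax(z))


class MarkovStateModel:
    """Markov state model estimated from discrete trajectories.

    Parameters
    ----------
    dtrajs : DiscreteTrajectory, list of DiscreteTrajectory or int arrays
    lag : int
        Lag time in frames.
    n_states : int, optional
        Total microstate count; inferred from the data if omitted.
    reversible : bool
        Maximum-likelihood estimation with detailed balance (default) or
        plain row normalisation of the counts.

    Examples
    --------
    >>> model = MarkovStateModel([dtraj], lag=20)      # doctest: +SKIP
    >>> res = model.fit()                              # doctest: +SKIP
    >>> res.stationary_distribution                    # doctest: +SKIP
    """

    def __init__(self, dtrajs, lag: int, n_states: int | None = None, reversible: bool = True):
        self.dtrajs = dtrajs if isinstance(dtrajs, list) else [dtrajs]
        self.lag = int(lag)
        self.reversible = bool(reversible)
        if n_states is None:
            sizes = [
                d.n_states if isinstance(d, DiscreteTrajectory) else int(np.max(d)) + 1
                for d in self.dtrajs
            ]
            n_states = max(sizes)
        self.n_states = int(n_states)
        intervals = {
            d.frame_interval for d in self.dtrajs if isinstance(d, DiscreteTrajectory)
        }
        self.frame_interval = intervals.pop() if len(intervals) == 1 else 1.0

    def fit(self) -> "MSMResults":
        C = count_matrix(self.dtrajs, self.lag, self.n_states)
        res = estimate_transition_model(
            C, lag=self.lag, reversible=self.reversible, frame_interval=self.frame_interval
        )
        res.model = self
        res.dtrajs = self.dtrajs
        return res


@dataclass
class MSMResults:
    """Fitted transition model.

    Attributes
    ----------
    counts : (k, k) count matrix over all microstates.
    active_set : indices of the largest strongly connected component.
    transition_matrix : row-stochastic matrix on the active set.
    eigenvalues : sorted descending, first is 1.
    stationary_distribution : length-k, zeros off the active set.
    """

    lag: int
    frame_interval: float
    n_states: int
    counts: np.ndarray
    active_set: np.ndarray
    transition_matrix: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors_right: np.ndarray
    stationary_distribution: np.ndarray
    reversible: bool
    model: MarkovStateModel | None = field(default=None, repr=False)
    dtrajs: list | None = field(default=None, repr=False)

    @property
    def lag_time(self) -> float:
        return self.lag * self.frame_interval

    def timescales(self, n: int | None = None) -> np.ndarray:
        """Implied timescales t_i = -lag_time / ln |lambda_{i+1}|.

        NaN where the eigenvalue is non-positive (or >= 1 to numerical
        precision), flagging rather than dropping the process.
        """
        lam = self.eigenvalues[1:]
        if n is not None:
            lam = lam[:n]
        lam = np.abs(np.asarray(lam, complex))
        with np.errstate(divide="ignore", invalid="ignore"):
            ts = -self.lag_time / np.log(lam)
        ts = np.where((lam <= 0) | (lam >= 1.0 - 1e-15), np.nan, ts.real)
        return ts

    def pcca(self, n_macro: int = 2, microstate_values=None, source: str = "reference"):
        return pcca(self, n_macro, microstate_values, source)

    def ck_test(self, macro: MacrostateDefinition, steps: int = 5) -> CKResult:
        """Chapman--Kolmogorov test on macrostate self-transition probabilities.

        Compares the prediction of this model propagated to lags m * tau
        (macrostate-aggregated powers of T) against models re-estimated at
        those lags, for m = 1 .. steps, with binomial-approximation error
        bars on the re-estimated values.
        """
        if steps < 1:
            raise EstimationError("ck_test requires steps >= 1")
        if self.dtrajs is None:
            raise EstimationError("ck_test needs the discrete trajectories (fit via MarkovStateModel)")
        names = macro.label_names
        pred = np.full((steps, len(names)), np.nan)
        est = np.full((steps, len(names)), np.nan)
        err = np.full((steps, len(names)), np.nan)
        pi = self.stationary_distribution
        pos = {s: i for i, s in enumerate(self.active_set)}
        for m in range(1, steps + 1):
            Tm = np.linalg.matrix_power(self.transition_matrix, m)
            for j, lab in enumerate(names):
                members = [pos[s] for s in macro.states(lab) if s in pos]
                if not members:
                    continue
                w = pi[self.active_set[members]]
                if w.sum() <= 0:
                    continue
                w = w / w.sum()
                pred[m - 1, j] = float(w @ Tm[np.ix_(members, members)].sum(axis=1))
            try:
                sub = MarkovStateModel(
                    self.dtrajs, self.lag * m, self.n_states, self.reversible
                ).fit()
            except EstimationError:
                continue  # insufficient data at this lag; row stays flagged NaN
            sub_pos = {s: i for i, s in enumerate(sub.active_set)}
            Cm = sub.counts
            for j, lab in enumerate(names):
                states = [s for s in macro.states(lab) if s in sub_pos]
                if not states:
                    continue
                members = [sub_pos[s] for s in states]
                w = sub.stationary_distribution[np.asarray(states)]
                if w.sum() <= 0:
                    continue
                w = w / w.sum()
                p = float(w @ sub.transition_matrix[np.ix_(members, members)].sum(axis=1))
                est[m - 1, j] = p
                n_obs = Cm[np.asarray(states)].sum()
                if n_obs > 0:
                    err[m - 1, j] = np.sqrt(max(p * (1.0 - p), 1e-12) / n_obs)
        lags = self.lag * np.arange(1, steps + 1)
        return CKResult(lags, names, pred, est, err)

    def summary(self) -> str:
        ts = self.timescales(min(5, len(self.eigenvalues) - 1))
        lines = [
            "Markov State Model Results",
            "=" * 42,
            f"microstates (total):        {self.n_states}",
            f"active set size:            {self.active_set.size}",
            f"lag (frames):               {self.lag}",
            f"lag time:                   {self.lag_time:g}",
            f"reversible MLE:             {self.reversible}",
            f"total counts:               {self.counts.sum():.0f}",
            "leading eigenvalues:        "
            + ", ".join(f"{np.real(v):.6f}" for v in self.eigenvalues[: min(5, len(self.eigenvalues))]),
            "implied timescales:         "
            + ", ".join("nan" if not np.isfinite(t) else f"{t:.4g}" for t in ts),
            f"stationary entropy:         "
            f"{-np.sum(np.where(self.stationary_distribution > 0, self.stationary_distribution * np.log(self.stationary_distribution), 0.0)):.4f}",
        ]
        return "\n".join(lines)


def estimate_transition_model(
    C: np.ndarray,
    lag: int = 1,
    reversible: bool = True,
    frame_interval: float = 1.0,
) -> MSMResults:
    """Estimate a transition model from a count matrix.

    The active set is the largest strongly connected component of the count
    graph; the transition matrix is reversible maximum likelihood (default)
    or row-normalised counts.  The stationary distribution is padded with
    zeros off the active set, matching the convention that microstates not
    visited by a system carry zero probability.
    """
    C = np.asarray(C, float)
    if np.any(C < 0):
        raise EstimationError("count matrix must be non-negative")
    k = C.shape[0]
    active = largest_connected_set(C)
    Ca = C[np.ix_(active, active)]
    if reversible:
        T, pi_a = _reversible_mle(Ca)
    else:
        rows = Ca.sum(axis=1)
        if np.any(rows <= 0):
            raise EstimationError("state with no outgoing counts inside the active set")
        T = Ca / rows[:, None]
        pi_a = _stationary_from_T(T)
    w, psi = _eigensystem(T, pi_a, reversible)
    pi = np.zeros(k)
    pi[active] = pi_a
    return MSMResults(
        lag=int(lag),
        frame_interval=float(frame_interval),
        n_states=k,
        counts=C,
        active_set=active,
        transition_matrix=T,
        eigenvalues=w,
        eigenvectors_right=psi,
        stationary_distribution=pi,
        reversible=reversible,
    )


def implied_timescales(
    dtrajs, lags, n_timescales: int = 5, reversible: bool = True
) -> pd.DataFrame:
    """Implied timescales over a range of lag times.

    Returns a tidy table with one row per lag and columns ``its_1`` ..
    ``its_n`` (in the trajectories' time unit).  Entries are NaN where the
    eigenvalue is non-positive or the data are insufficient at that lag --
    flagged, not dropped.
    """
    rows = []
    for lag in lags:
        row = {"lag": int(lag)}
        try:
            res = MarkovStateModel(
                dtrajs if isinstance(dtrajs, list) else [dtrajs], int(lag),
                reversible=reversible,
            ).fit()
            ts = res.timescales(n_timescales)
        except EstimationError:
            ts = np.full(n_timescales, np.nan)
        for i in range(n_timescales):
            row[f"its_{i + 1}"] = ts[i] if i < len(ts) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
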