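"""End-to-end protocol orchestration from a single configuration.

The pipeline mirrors a steered-then-seeded sampling strategy: for every
system, a steering trajectory is driven in each direction between the two
declared basins; snapshots evenly sampling the steered coordinate seed a
swarm of equilibrium trajectories; all systems' swarms are pooled into one
k-means microstate model; a transition model is estimated per system at a
common lag; the reference system's PCCA partition defines the active and
inactive macrostates for everyone (reference-unsampled microstates are
inactive); active-state probabilities are bootstrapped per system and each
ligand system is classified against the reference distribution.

All randomness derives from a single master seed; rerunning the same
configuration reproduces every numeric output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .compare import (
    ActiveStateDistribution,
    EffectCall,
    SystemEnsemble,
    bootstrap_distribution,
    classify_effect,
    pool_and_cluster,
    transfer_macrostates,
)
from .dynamics import (
    FlatBottomRestraint,
    LangevinParams,
    SteeringSchedule,
    simulate,
    trajectory_seed,
)
from .errors import ConfigurationError, AllostateError
from .msm import MacrostateDefinition, MarkovStateModel, MSMResults, implied_timescales
from .potentials import PotentialSpec
from .seeding import extract_seeds

__all__ = [
    "ProtocolConfig",
    "SystemSpec",
    "ProtocolReport",
    "load_config",
    "run_protocol",
    "toy_experiment_config",
]

log = logging.getLogger("allostate.workflow")

# printed protocol defaults: 100 seeds per steering direction, 5000 saved
# frames per seeded trajectory, 100 microstates, lag 2000 frames, 100
# bootstrap iterations over 200 resampled trajectories
_DEFAULTS = {
    "n_seeds": 100,
    "seeded_frames": 5000,
    "k_microstates": 100,
    "lag": 2000,
    "its_lags": [1, 2, 5, 10, 20, 50, 100, 200, 500, 1000, 2000, 3000],
    "reversible": True,
    "n_macro": 2,
    "n_iter": 100,
    "n_traj": 200,
    "delta": 0.05,
    "ck_steps": 5,
    "master_seed": 0,
}

_STEER_DEFAULTS = {"cv_index": 0, "k": 25.0, "ramp_steps": 800, "total_steps": 20000}
_LANGEVIN_DEFAULTS = {"dt": 0.008, "temperature": 1.0, "friction": 1.0, "save_stride": 10}


@dataclass
class SystemSpec:
    """A toy system: its potential and optional flat-bottom restraints."""

    label: str
    potential: PotentialSpec
    restraints: tuple[FlatBottomRestraint, ...] = ()


@dataclass
class ProtocolConfig:
    systems: dict[str, SystemSpec] = field(default_factory=dict)
    reference: str | None = None
    steering: dict = field(default_factory=lambda: dict(_STEER_DEFAULTS))
    langevin: dict = field(default_factory=lambda: dict(_LANGEVIN_DEFAULTS))
    n_seeds: int = _DEFAULTS["n_seeds"]
    seeded_frames: int = _DEFAULTS["seeded_frames"]
    k_microstates: int = _DEFAULTS["k_microstates"]
    lag: int = _DEFAULTS["lag"]
    its_lags: list = field(default_factory=lambda: list(_DEFAULTS["its_lags"]))
    reversible: bool = True
    n_macro: int = 2
    n_iter: int = _DEFAULTS["n_iter"]
    n_traj: int = _DEFAULTS["n_traj"]
    delta: float = _DEFAULTS["delta"]
    ck_steps: int = _DEFAULTS["ck_steps"]
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_seeds", "seeded_frames", "k_microstates", "lag", "n_macro",
                     "n_iter", "n_traj", "ck_steps"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1 (got {getattr(self, name)})")
        if self.delta < 0:
            raise ConfigurationError("delta must be >= 0")
        if any(int(l) < 1 for l in self.its_lags):
            raise ConfigurationError("its_lags must be positive")
        if self.reference is not None and self.systems and self.reference not in self.systems:
            raise ConfigurationError(f"reference {self.reference!r} is not a configured system")

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "systems": {
                lbl: {
                    "potential": {
                        "kind": s.potential.kind,
                        "minima": [list(m) for m in s.potential.minima],
                        "depths": list(s.potential.depths),
                        "barrier_scale": s.potential.barrier_scale,
                        "coupling": s.potential.coupling,
                        "stiffness": s.potential.stiffness,
                    },
                    "restraints": [
                        {"cv_index": r.cv_index, "lower": r.lower, "upper": r.upper, "k": r.k}
                        for r in s.restraints
                    ],
                }
                for lbl, s in self.systems.items()
            },
            "steering": dict(self.steering),
            "langevin": dict(self.langevin),
            **{k: getattr(self, k) for k in _DEFAULTS if k not in ("its_lags",)},
            "its_lags": list(self.its_lags),
        }


def _check_keys(mapping: dict, allowed, context: str) -> None:
    unknown = set(mapping) - set(allowed)
    if unknown:
        raise ConfigurationError(f"unknown key(s) in {context}: {sorted(unknown)}")


def _parse_system(label: str, raw: dict) -> SystemSpec:
    _check_keys(raw, {"potential", "restraints"}, f"system {label!r}")
    pot_raw = raw.get("potential")
    if pot_raw is None:
        raise ConfigurationError(f"system {label!r} needs a potential")
    _check_keys(
        pot_raw,
        {"kind", "minima", "depths", "barrier_scale", "coupling", "stiffness"},
        f"system {label!r} potential",
    )
    potential = PotentialSpec(**pot_raw)
    restraints = []
    for r in raw.get("restraints", []) or []:
        _check_keys(r, {"cv_index", "lower", "upper", "k"}, f"system {label!r} restraint")
        restraints.append(FlatBottomRestraint(**r))
    return SystemSpec(label, potential, tuple(restraints))


def load_config(path) -> ProtocolConfig:
    """Load a YAML protocol configuration; unknown keys are rejected.

    Missing keys take the protocol defaults (100 seeds per steering
    direction, 100 microstates, lag 2000 frames, 100 bootstrap iterations
    over 200 trajectories, ...).  The fully resolved configuration is
    echoed to the log.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("configuration must be a mapping")
    allowed = set(_DEFAULTS) | {"systems", "reference", "steering", "langevin"}
    _check_keys(raw, allowed, "configuration")

    steering = dict(_STEER_DEFAULTS)
    if "steering" in raw:
        _check_keys(raw["steering"], set(_STEER_DEFAULTS), "steering")
        steering.update(raw["steering"])
    langevin = dict(_LANGEVIN_DEFAULTS)
    if "langevin" in raw:
        _check_keys(raw["langevin"], set(_LANGEVIN_DEFAULTS), "langevin")
        langevin.update(raw["langevin"])

    systems = {
        lbl: _parse_system(lbl, sysraw) for lbl, sysraw in (raw.get("systems") or {}).items()
    }
    reference = raw.get("reference")
    if reference is None and systems:
        if "reference" in systems:
            reference = "reference"
        else:
            raise ConfigurationError("a multi-system config must name its reference system")

    kwargs = {k: raw.get(k, v) for k, v in _DEFAULTS.items()}
    cfg = ProtocolConfig(
        systems=systems, reference=reference, steering=steering, langevin=langevin, **kwargs
    )
    log.info("resolved configuration: %s", json.dumps(cfg.to_dict(), sort_keys=True))
    return cfg


@dataclass
class ProtocolReport:
    """Everything the protocol produced for one run."""

    config: ProtocolConfig
    cluster_centers: np.ndarray
    reference_macro: MacrostateDefinition
    results: dict[str, MSMResults]
    distributions: dict[str, ActiveStateDistribution]
    calls: dict[str, EffectCall]
    its: "object"  # DataFrame of reference implied timescales
    ck: "object"  # CKResult of the reference model
    artifacts: dict[str, str] = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Protocol report", "=" * 42]
        for lbl, dist in self.distributions.items():
            mark = " (reference)" if lbl == self.config.reference else ""
            lines.append(
                f"{lbl}{mark}: median active-state probability {dist.median:.3f} "
                f"[{dist.values.min():.3f}, {dist.values.max():.3f}]"
            )
        for call in self.calls.values():
            lines.append(str(call))
        return "\n".join(lines)


def toy_experiment_config(
    master_seed: int = 0,
    active_destabilization: float = 0.0,
    ligand_label: str = "ligand",
    **overrides,
) -> ProtocolConfig:
    """Desk-scale two-system study: reference vs modified active basin.

    Both systems share a two-basin landscape whose first basin (low
    first-feature value, the "active" conformation) sits at (0.5, 0.3) and
    whose second ("inactive") at (2.5, 0.9), with a 2.2 kT barrier and
    symmetric 3.5 kT depths.  ``active_destabilization`` raises the active
    basin of the ligand system by that many kT, emulating an allosteric
    inhibitor that disfavours the active conformation; 0 gives a zero-shift
    control.  The sampling scale (2 x 30 seeds, 60 trajectories of 2000
    frames per system, 30 microstates, lag 10 frames, 40 bootstrap
    iterations over 60 trajectories) is sized so the bootstrap medians
    resolve shifts well below the 0.05 classification threshold.
    """

    def spec(label: str, destab: float) -> SystemSpec:
        return SystemSpec(
            label,
            PotentialSpec(
                "double_well_2d",
                minima=[(0.5, 0.3), (2.5, 0.9)],
                depths=(3.5 - destab, 3.5),
                barrier_scale=2.2,
            ),
        )

    kwargs = dict(
        systems={
            "reference": spec("reference", 0.0),
            ligand_label: spec(ligand_label, active_destabilization),
        },
        reference="reference",
        steering={"cv_index": 0, "k": 25.0, "ramp_steps": 200, "total_steps": 5000},
        langevin={"dt": 0.008, "temperature": 1.0, "friction": 1.0, "save_stride": 10},
        n_seeds=30,
        seeded_frames=2000,
        k_microstates=30,
        lag=10,
        its_lags=[1, 2, 5, 10, 20, 50],
        n_iter=40,
        n_traj=60,
        ck_steps=5,
        master_seed=master_seed,
    )
    kwargs.update(overrides)
    return ProtocolConfig(**kwargs)


def _system_stream(master_seed: int, label: str) -> int:
    """Order- and presence-independent per-system seed root."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(label.encode())])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _stage(name: str, system: str):
    log.info("stage=%s system=%s", name, system)


def _simulate_system(cfg: ProtocolConfig, spec: SystemSpec) -> SystemEnsemble:
    """Steer both directions, seed, and run the equilibrium swarm."""
    lv = cfg.langevin
    st = cfg.steering
    cv = int(st["cv_index"])
    root = _system_stream(cfg.master_seed, spec.label)
    minima = spec.potential.minima
    if len(minima) < 2:
        raise ConfigurationError(
            f"system {spec.label!r}: steering needs a two-basin potential"
        )

    _stage("steering", spec.label)
    steer_trajs = []
    for direction, (a, b) in enumerate([(minima[0], minima[1]), (minima[1], minima[0])]):
        schedule = SteeringSchedule(
            cv_index=cv,
            ramp_steps=int(st["ramp_steps"]),
            k=float(st["k"]),
            start_value=float(a[cv]),
            target_value=float(b[cv]),
            total_steps=int(st["total_steps"]),
        )
        params = LangevinParams(
            dt=float(lv["dt"]),
            temperature=float(lv["temperature"]),
            friction=float(lv["friction"]),
            n_steps=int(st["total_steps"]),
            save_stride=1,
            seed=trajectory_seed(root, direction),
        )
        steer_trajs.append(
            simulate(
                spec.potential, params, schedule, spec.restraints, x0=a,
                label=f"{spec.label}/steer_{direction}",
            )
        )

    _stage("seeding", spec.label)
    coord = f"feature_{cv + 1}"
    seed_points = []
    # interleave the two steering directions
    seed_sets = [extract_seeds(t, coord, cfg.n_seeds) for t in steer_trajs]
    for i in range(cfg.n_seeds):
        for s_set, traj in zip(seed_sets, steer_trajs):
            seed_points.append(traj.values[s_set.frames[i]])

    _stage("swarm", spec.label)
    params = dict(
        dt=float(lv["dt"]),
        temperature=float(lv["temperature"]),
        friction=float(lv["friction"]),
        n_steps=int(cfg.seeded_frames) * int(lv["save_stride"]),
        save_stride=int(lv["save_stride"]),
    )
    swarm = []
    for i, point in enumerate(seed_points):
        p = LangevinParams(**params, seed=trajectory_seed(root, 2 + i))
        swarm.append(
            simulate(
                spec.potential, p, None, spec.restraints, x0=point,
                label=f"{spec.label}/seed_{i}",
            )
        )
    return SystemEnsemble(spec.label, swarm)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_protocol(config: ProtocolConfig, outdir=None) -> ProtocolReport:
    """Run the full protocol: steer, seed, swarm, cluster, model, compare.

    The reference system is processed first; all other systems are
    classified against it.  With a single system only its distribution is
    returned, with a warning.  If ``outdir`` is given every derived table
    is written there along with a manifest of content hashes.
    """
    if not config.systems:
        raise ConfigurationError("no systems configured")
    labels = list(config.systems)
    reference = config.reference if config.reference is not None else labels[0]
    order = [reference] + sorted(l for l in labels if l != reference)

    ensembles: dict[str, SystemEnsemble] = {}
    for lbl in order:
        try:
            ensembles[lbl] = _simulate_system(config, config.systems[lbl])
        except AllostateError as exc:
            raise type(exc)(f"stage simulate failed for system {lbl!r}: {exc}") from exc

    _stage("cluster", "pooled")
    cluster_seed = _system_stream(config.master_seed, "__cluster__")
    cluster_model = pool_and_cluster(
        [ensembles[l] for l in order], config.k_microstates, cluster_seed
    )

    results: dict[str, MSMResults] = {}
    dtrajs_by_system = {}
    for lbl in order:
        _stage("msm", lbl)
        dtrajs = ensembles[lbl].discretize(cluster_model)
        dtrajs_by_system[lbl] = dtrajs
        try:
            results[lbl] = MarkovStateModel(
                dtrajs, config.lag, cluster_model.n_states, config.reversible
            ).fit()
        except AllostateError as exc:
            raise type(exc)(f"stage msm failed for system {lbl!r}: {exc}") from exc

    _stage("pcca", reference)
    ref_macro = results[reference].pcca(
        config.n_macro, cluster_model.centers[:, 0], source=reference
    )
    macro = transfer_macrostates(ref_macro)

    _stage("its", reference)
    feasible_lags = [l for l in config.its_lags if l < config.seeded_frames]
    its = implied_timescales(
        dtrajs_by_system[reference], feasible_lags, n_timescales=min(4, config.k_microstates - 1),
        reversible=config.reversible,
    )
    _stage("ck", reference)
    ck = results[reference].ck_test(macro, config.ck_steps)

    distributions: dict[str, ActiveStateDistribution] = {}
    for lbl in order:
        _stage("bootstrap", lbl)
        distributions[lbl] = bootstrap_distribution(
            dtrajs_by_system[lbl],
            None,
            macro,
            config.lag,
            n_iter=config.n_iter,
            n_traj=config.n_traj,
            seed=_system_stream(config.master_seed, f"bootstrap/{lbl}"),
            reversible=config.reversible,
            label=lbl,
        )

    calls: dict[str, EffectCall] = {}
    if len(order) == 1:
        warnings.warn(
            "single-system run: distributions computed, no effect labels", stacklevel=2
        )
    else:
        for lbl in order[1:]:
            _stage("classify", lbl)
            calls[lbl] = classify_effect(
                distributions[lbl], distributions[reference], config.delta
            )

    report = ProtocolReport(
        config=config,
        cluster_centers=cluster_model.centers,
        reference_macro=macro,
        results=results,
        distributions=distributions,
        calls=calls,
        its=its,
        ck=ck,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        (outdir / "config.yaml").write_text(
            yaml.safe_dump(config.to_dict(), sort_keys=True)
        )
        paths["config"] = outdir / "config.yaml"
        cluster_model.write(outdir / "cluster_centers.csv")
        paths["cluster_centers"] = outdir / "cluster_centers.csv"
        macro.write(outdir / "macrostates.csv")
        paths["macrostates"] = outdir / "macrostates.csv"
        its.to_csv(outdir / "implied_timescales.csv", index=False, float_format="%.10g")
        paths["implied_timescales"] = outdir / "implied_timescales.csv"
        ck.to_dataframe().to_csv(outdir / "ck_test.csv", index=False, float_format="%.10g")
        paths["ck_test"] = outdir / "ck_test.csv"
        for lbl, dist in distributions.items():
            p = outdir / f"bootstrap_{lbl}.csv"
            dist.write(p)
            paths[f"bootstrap_{lbl}"] = p
        report_data = {
            "reference": reference,
            "medians": {l: d.median for l, d in distributions.items()},
            "calls": {
                l: {
                    "label": c.label,
                    "shift": c.shift,
                    "overlap_fraction": c.overlap_fraction,
                }
                for l, c in calls.items()
            },
        }
        (outdir / "report.json").write_text(json.dumps(report_data, indent=2, sort_keys=True))
        paths["report"] = outdir / "report.json"
        manifest = {name: _sha256(p) for name, p in sorted(paths.items())}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        report.artifacts = {name: str(p) for name, p in paths.items()}

    return report
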