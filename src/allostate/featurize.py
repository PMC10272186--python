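"""Reduce coordinate trajectories to low-dimensional feature space.

Supports the three featurizers needed for catalytic-loop analysis:
superposition (Kabsch) RMSD of an atom selection to a reference
conformation, atom-pair distances, and signed dihedral angles.  Coordinate
input is multi-model PDB (parsed with biotite) or plain XYZ; featurized
output is a :class:`~allostate.trajectories.FeatureTrajectory`.

Conventions: "backbone" means atoms N, CA, C, O; residue numbers are
1-based as in PDB records; dihedrals follow the IUPAC sign convention
(positive = clockwise rotation of the far bond viewed along the central
bond), range (-180, 180] degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, GeometryError, SelectionError
from .trajectories import FeatureTrajectory

__all__ = [
    "CoordinateTrajectory",
    "FeatureSpec",
    "read_trajectory",
    "kabsch_rmsd",
    "pair_distance",
    "dihedral",
    "featurize_trajectory",
    "BACKBONE_ATOMS",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class CoordinateTrajectory:
    """Cartesian frames (Angstrom) with atom names and 1-based residue ids."""

    coords: np.ndarray  # (n_frames, n_atoms, 3)
    atom_names: list[str]
    res_ids: np.ndarray  # (n_atoms,) int
    frame_interval: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atom_names) or len(self.atom_names) != len(
            self.res_ids
        ):
            raise FormatError("atom labels must match the atom count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_index(self, res_id: int, atom_name: str) -> int:
        hits = np.flatnonzero((self.res_ids == res_id) & (np.asarray(self.atom_names) == atom_name))
        if hits.size == 0:
            raise SelectionError(f"no atom {atom_name!r} in residue {res_id}")
        return int(hits[0])

    def select(self, selection) -> np.ndarray:
        """Resolve a list of (res_id, atom_name) pairs to atom indices."""
        return np.array([self.atom_index(r, a) for r, a in selection], dtype=int)


@dataclass
class FeatureSpec:
    """One feature column: kind, atom selection, optional RMSD reference.

    ``selection`` is a list of (residue id, atom name) pairs; a dihedral
    selection must contain exactly four atoms.  ``reference`` holds the
    already-selected reference coordinates, shape (n_sel, 3), for
    ``rmsd_to_reference``.
    """

    kind: str  # rmsd_to_reference | pair_distance | dihedral
    selection: list = field(default_factory=list)
    reference: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("rmsd_to_reference", "pair_distance", "dihedral"):
            raise SelectionError(f"unknown feature kind {self.kind!r}")
        if self.kind == "dihedral" and len(self.selection) != 4:
            raise SelectionError("a dihedral selection must contain exactly 4 atoms")
        if self.kind == "pair_distance" and len(self.selection) != 2:
            raise SelectionError("a pair-distance selection must contain exactly 2 atoms")
        if self.kind == "rmsd_to_reference":
            if self.reference is None:
                raise SelectionError("rmsd_to_reference requires reference coordinates")
            self.reference = np.asarray(self.reference, float)
            if len(self.selection) < 1:
                raise SelectionError("rmsd selection must contain at least 1 atom")
            if self.reference.shape != (len(self.selection), 3):
                raise SelectionError("reference must match the selection, shape (n_sel, 3)")
        if not self.name:
            self.name = self.kind


def _read_pdb_multimodel(path: Path) -> CoordinateTrajectory:
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise FormatError(f"{path}: no MODEL records or coordinates found")
    frames = []
    names: list[str] | None = None
    res_ids = None
    for m in range(1, n_models + 1):
        atoms = pdb.get_structure(model=m)
        if names is None:
            names = list(atoms.atom_name)
            res_ids = np.asarray(atoms.res_id, int)
        elif atoms.array_length() != len(names):
            raise FormatError(
                f"{path}: MODEL {m} has {atoms.array_length()} atoms, "
                f"expected {len(names)} (frame {m - 1})"
            )
        frames.append(np.asarray(atoms.coord, float))
    return CoordinateTrajectory(np.stack(frames), names, res_ids, label=path.stem)


def _read_xyz(path: Path) -> CoordinateTrajectory:
    """Plain multi-frame XYZ: count line, comment line, then atom lines."""
    lines = path.read_text().splitlines()
    frames = []
    names: list[str] | None = None
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(f"{path}: expected atom count at line {i + 1}") from exc
        if i + 2 + n > len(lines):
            raise FormatError(f"{path}: truncated frame {frame_no}")
        block = lines[i + 2 : i + 2 + n]
        fnames, coords = [], []
        for line in block:
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}: bad atom line in frame {frame_no}: {line!r}")
            fnames.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        if names is None:
            names = fnames
        elif fnames != names:
            raise FormatError(f"{path}: atom list changed at frame {frame_no}")
        frames.append(np.asarray(coords))
        i += 2 + n
        frame_no += 1
    if not frames:
        raise FormatError(f"{path}: empty XYZ file")
    return CoordinateTrajectory(
        np.stack(frames), names, np.arange(1, len(names) + 1), label=path.stem
    )


def read_trajectory(path, format: str) -> CoordinateTrajectory | FeatureTrajectory:
    """Read a trajectory file.

    ``format`` is one of ``pdb_multimodel``, ``xyz`` (both return a
    :class:`CoordinateTrajectory`) or ``feature_table`` (returns a
    :class:`~allostate.trajectories.FeatureTrajectory`).  Frames are kept
    in file order; PDB MODEL records map one-to-one to frames.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "pdb_multimodel":
        return _read_pdb_multimodel(path)
    if format == "xyz":
        return _read_xyz(path)
    if format == "feature_table":
        return FeatureTrajectory.read(path)
    raise FormatError(f"unknown trajectory format {format!r}")


def kabsch_rmsd(reference: np.ndarray, frame: np.ndarray, selection=None) -> float:
    """Minimum RMSD (Angstrom) over rigid superposition of the selection.

    The optimal rotation is found with the Kabsch algorithm after centroid
    alignment; the fit set equals the measured set.  With fewer than three
    non-collinear atoms the superposition is degenerate: a warning is issued
    and a translation-only (centroid) fit is used.
    """
    ref = np.asarray(reference, float)
    frm = np.asarray(frame, float)
    if selection is not None:
        sel = np.asarray(selection, int)
        ref = ref[sel]
        frm = frm[sel]
    if ref.shape != frm.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise SelectionError("reference and frame selections must share shape (n, 3)")
    if ref.shape[0] < 1:
        raise SelectionError("empty selection")
    ref_c = ref - ref.mean(axis=0)
    frm_c = frm - frm.mean(axis=0)
    n = ref.shape[0]
    if n < 3 or np.linalg.matrix_rank(ref_c, tol=1e-9) < 2:
        warnings.warn(
            "fewer than 3 non-collinear atoms: degenerate superposition, "
            "translation-only fit",
            stacklevel=2,
        )
        return float(np.sqrt(np.mean(np.sum((ref_c - frm_c) ** 2, axis=1))))
    # Kabsch rotation via SVD; residual evaluated on the superposed
    # coordinates (avoids the cancellation error of rssd-style formulas)
    H = frm_c.T @ ref_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    diff = ref_c - frm_c @ R.T
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def pair_distance(frame: np.ndarray, atom_a: int, atom_b: int) -> float:
    """Euclidean distance (Angstrom) between two atoms of a frame."""
    frame = np.asarray(frame, float)
    try:
        a = frame[atom_a]
        b = frame[atom_b]
    except IndexError as exc:
        raise SelectionError(f"atom index out of range: {atom_a}, {atom_b}") from exc
    return float(np.linalg.norm(a - b))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle (degrees, range (-180, 180]) of four points.

    IUPAC convention: looking along the central bond p1 -> p2, a clockwise
    rotation of the far bond relative to the near bond is positive.  A
    planar trans arrangement gives +180, cis gives 0.
    """
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    if np.linalg.norm(b1) < 1e-12 or np.linalg.norm(b2) < 1e-12 or np.linalg.norm(b3) < 1e-12:
        raise GeometryError("consecutive dihedral points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise GeometryError("degenerate dihedral: parallel bond vectors")
    b2u = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, b2u), n2))
    angle = np.degrees(np.arctan2(y, x))
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


def featurize_trajectory(traj: CoordinateTrajectory, specs) -> FeatureTrajectory:
    """Apply feature specs to every frame; one column per spec, in order."""
    cols = []
    names = []
    for spec in specs:
        idx = traj.select(spec.selection) if spec.kind != "pair_distance" else None
        values = np.empty(traj.n_frames)
        for f in range(traj.n_frames):
            frame = traj.coords[f]
            try:
                if spec.kind == "rmsd_to_reference":
                    values[f] = kabsch_rmsd(spec.reference, frame[idx])
                elif spec.kind == "pair_distance":
                    a = traj.atom_index(*spec.selection[0])
                    b = traj.atom_index(*spec.selection[1])
                    values[f] = pair_distance(frame, a, b)
                else:
                    values[f] = dihedral(*frame[idx])
            except (GeometryError, SelectionError) as exc:
                raise type(exc)(f"frame {f}, feature {spec.name!r}: {exc}") from exc
        cols.append(values)
        names.append(spec.name)
    return FeatureTrajectory(
        np.column_stack(cols), names, frame_interval=traj.frame_interval, label=traj.label
    )
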