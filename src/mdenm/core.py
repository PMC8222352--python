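"""Domain types, coordinate I/O and superposition/RMSD/RMSF primitives.

Conventions used throughout the package:

* coordinates are in Å, flattened to length-3N vectors (atom-major);
* masses are in atomic mass units;
* energies are in kcal/mol, time in ps, so velocities are Å/ps and kinetic
  energies need the kcal/mol <-> amu·Å²/ps² conversion in :data:`KCAL_TO_AKMA`;
* RMSD/RMSF over a selection are unweighted (mass-weighting is used only
  inside the normal-mode analysis).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb
from scipy.spatial.transform import Rotation

__all__ = [
    "KB_KCAL",
    "KCAL_TO_AKMA",
    "AtomLabel",
    "Structure",
    "SelectionSpec",
    "Ensemble",
    "PDBParseError",
    "read_structure",
    "read_ensemble",
    "write_structure",
    "write_ensemble",
    "read_trajectory_table",
    "write_trajectory_table",
    "superpose",
    "rmsd",
    "rmsd_series",
    "rmsf",
]

#: Boltzmann constant in kcal/(mol·K).
KB_KCAL = 0.0019872041

#: 1 kcal/mol expressed in amu·Å²/ps² (4184 J/mol divided by 10 J/mol).
KCAL_TO_AKMA = 418.4

# Fallback element masses (amu) for elements biotite cannot resolve.
_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "P": 30.974, "S": 32.06, "SE": 78.971, "FE": 55.845,
}
_DEFAULT_MASS = 12.011  # explicit default: treat unknown elements as carbon


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed; the message names the line."""


@dataclass(frozen=True)
class AtomLabel:
    residue_index: int
    residue_name: str
    atom_name: str


@dataclass
class Structure:
    """Labeled 3-D point set with masses; the unit of superposition and NMA.

    ``coords`` is the flattened length-3N position vector in Å; ``masses``
    has length N in amu.
    """

    atom_labels: list[AtomLabel]
    coords: np.ndarray
    masses: np.ndarray
    elements: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).ravel()
        self.masses = np.asarray(self.masses, dtype=float).ravel()
        n = len(self.atom_labels)
        if self.coords.size != 3 * n:
            raise ValueError(
                f"coords length {self.coords.size} != 3 x {n} atoms"
            )
        if self.masses.size != n:
            raise ValueError("one mass per atom required")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be strictly positive")
        res = [lab.residue_index for lab in self.atom_labels]
        if any(b < a for a, b in zip(res, res[1:])):
            raise ValueError("residue indices must be non-decreasing")
        if not self.elements:
            self.elements = ["C"] * n

    @property
    def n_atoms(self) -> int:
        return len(self.atom_labels)

    @property
    def xyz(self) -> np.ndarray:
        """Coordinates as an (N, 3) view."""
        return self.coords.reshape(-1, 3)

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        for i, lab in enumerate(self.atom_labels):
            if lab.residue_index == residue_index and lab.atom_name == atom_name:
                return i
        raise KeyError(
            f"atom {atom_name} of residue {residue_index} not in structure"
        )

    def select(self, pairs: Iterable[tuple[int, str]]) -> np.ndarray:
        """Resolve (residue_index, atom_name) pairs to atom indices."""
        return np.array([self.atom_index(r, a) for r, a in pairs], dtype=int)


@dataclass
class SelectionSpec:
    """Names the binding-pocket atoms and the three loop-tip atoms.

    ``tips`` maps the loop identifiers L1/L2/L3 to (residue_index, atom_name);
    the two monitored gate distances are d(L1,L2) and d(L1,L3).
    """

    pocket: list[tuple[int, str]]
    tips: dict[str, tuple[int, str]]

    def __post_init__(self) -> None:
        if not self.pocket:
            raise ValueError("pocket selection must be non-empty")
        if set(self.tips) != {"L1", "L2", "L3"}:
            raise ValueError("tips must name exactly L1, L2 and L3")
        if len(set(self.tips.values())) != 3:
            raise ValueError("tip atoms must be distinct")

    def pocket_indices(self, structure: Structure) -> np.ndarray:
        return structure.select(self.pocket)

    def tip_indices(self, structure: Structure) -> dict[str, int]:
        return {
            loop: structure.atom_index(r, a) for loop, (r, a) in self.tips.items()
        }


@dataclass
class Ensemble:
    """Ordered conformations conformable with a reference Structure.

    ``frames`` is an (n_frames, 3N) array; ``provenance`` carries per-frame
    (source, replica, time_ps) with source one of MD / MDeNM / other.
    """

    frames: np.ndarray
    source: list[str] = field(default_factory=list)
    replica: np.ndarray | None = None
    time_ps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=float))
        n = self.n_frames
        if not self.source:
            self.source = ["other"] * n
        if self.replica is None:
            self.replica = np.zeros(n, dtype=int)
        if self.time_ps is None:
            self.time_ps = np.zeros(n, dtype=float)
        self.replica = np.asarray(self.replica, dtype=int)
        self.time_ps = np.asarray(self.time_ps, dtype=float)
        if not (len(self.source) == self.replica.size == self.time_ps.size == n):
            raise ValueError("provenance arrays must match frame count")
        if np.any(self.time_ps < 0):
            raise ValueError("time_ps must be non-negative")
        for rep in np.unique(self.replica):
            t = self.time_ps[self.replica == rep]
            if np.any(np.diff(t) < 0):
                raise ValueError(f"time_ps not non-decreasing in replica {rep}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def xyz(self, frame: int) -> np.ndarray:
        return self.frames[frame].reshape(-1, 3)

    @classmethod
    def concatenate(cls, ensembles: Sequence["Ensemble"]) -> "Ensemble":
        return cls(
            frames=np.vstack([e.frames for e in ensembles]),
            source=sum((list(e.source) for e in ensembles), []),
            replica=np.concatenate([e.replica for e in ensembles]),
            time_ps=np.concatenate([e.time_ps for e in ensembles]),
        )


# ---------------------------------------------------------------------------
# PDB I/O (biotite backend with line-level validation)
# ---------------------------------------------------------------------------

def _validate_pdb_lines(path: str) -> None:
    """Raise :class:`PDBParseError` naming the first malformed ATOM line."""
    n_atoms = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                n_atoms += 1
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError(
                        f"{path}: truncated {rec} record at line {lineno}"
                    )
                try:
                    for lo, hi in ((30, 38), (38, 46), (46, 54)):
                        float(line[lo:hi])
                except ValueError:
                    raise PDBParseError(
                        f"{path}: unreadable coordinates at line {lineno}"
                    ) from None
    if n_atoms == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records (empty input)")


def _mass_for(element: str, atom_name: str) -> float:
    element = element.strip().upper()
    if not element:
        # infer from the first letter of the atom name
        element = atom_name.strip().lstrip("0123456789")[:1].upper()
    try:
        m = bst.info.mass(element)
        if m is not None:
            return float(m)
    except KeyError:
        pass
    return _ELEMENT_MASSES.get(element, _DEFAULT_MASS)


def _atom_array_to_structure(arr: bst.AtomArray) -> Structure:
    labels = [
        AtomLabel(int(r), str(rn), str(an))
        for r, rn, an in zip(arr.res_id, arr.res_name, arr.atom_name)
    ]
    elements = [str(e) for e in arr.element]
    masses = np.array(
        [_mass_for(e, lab.atom_name) for e, lab in zip(elements, labels)]
    )
    return Structure(labels, arr.coord.ravel().copy(), masses, elements)


def read_structure(path: str) -> Structure:
    """Read the first model of a PDB file as a :class:`Structure`."""
    _validate_pdb_lines(path)
    pdb = bpdb.PDBFile.read(path)
    arr = pdb.get_structure(model=1, altloc="first")
    return _atom_array_to_structure(arr)


def read_ensemble(path: str) -> tuple[Structure, Ensemble]:
    """Read a (possibly multi-MODEL) PDB file as reference + ensemble."""
    _validate_pdb_lines(path)
    pdb = bpdb.PDBFile.read(path)
    stack = pdb.get_structure(altloc="first")
    if isinstance(stack, bst.AtomArray):  # single model
        stack = bst.stack([stack])
    ref = _atom_array_to_structure(stack[0])
    frames = stack.coord.reshape(stack.stack_depth(), -1).copy()
    return ref, Ensemble(frames=frames)


def _structure_to_atom_array(structure: Structure) -> bst.AtomArray:
    n = structure.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = structure.xyz.astype(np.float32)
    arr.res_id = np.array([l.residue_index for l in structure.atom_labels])
    arr.res_name = np.array([l.residue_name for l in structure.atom_labels])
    arr.atom_name = np.array([l.atom_name for l in structure.atom_labels])
    arr.chain_id = np.array(["A"] * n)
    arr.element = np.array(structure.elements)
    arr.hetero = np.array([False] * n)
    return arr


def write_structure(structure: Structure, path: str) -> None:
    pdb = bpdb.PDBFile()
    pdb.set_structure(_structure_to_atom_array(structure))
    pdb.write(path)


def write_ensemble(structure: Structure, ensemble: Ensemble, path: str) -> None:
    """Write an ensemble as a multi-MODEL PDB using ``structure`` labels."""
    template = _structure_to_atom_array(structure)
    stack = bst.stack([template] * ensemble.n_frames)
    stack.coord = ensemble.frames.reshape(
        ensemble.n_frames, -1, 3
    ).astype(np.float32)
    pdb = bpdb.PDBFile()
    pdb.set_structure(stack)
    pdb.write(path)


def write_trajectory_table(ensemble: Ensemble, path: str) -> None:
    """Serialize an ensemble as a delimited (frame, atom, x, y, z) table."""
    import pandas as pd

    n_frames = ensemble.n_frames
    n_atoms = ensemble.frames.shape[1] // 3
    xyz = ensemble.frames.reshape(n_frames, n_atoms, 3)
    frame_idx = np.repeat(np.arange(n_frames), n_atoms)
    df = pd.DataFrame(
        {
            "frame": frame_idx,
            "atom": np.tile(np.arange(n_atoms), n_frames),
            "x": xyz[:, :, 0].ravel(),
            "y": xyz[:, :, 1].ravel(),
            "z": xyz[:, :, 2].ravel(),
            "source": np.repeat(ensemble.source, n_atoms),
            "replica": np.repeat(ensemble.replica, n_atoms),
            "time_ps": np.repeat(ensemble.time_ps, n_atoms),
        }
    )
    df.to_csv(path, index=False)


def read_trajectory_table(path: str) -> Ensemble:
    import pandas as pd

    df = pd.read_csv(path)
    n_frames = df["frame"].nunique()
    n_atoms = df["atom"].nunique()
    df = df.sort_values(["frame", "atom"], kind="stable")
    frames = df[["x", "y", "z"]].to_numpy().reshape(n_frames, 3 * n_atoms)
    per_frame = df.drop_duplicates("frame")
    return Ensemble(
        frames=frames,
        source=list(per_frame.get("source", pd.Series(["other"] * n_frames))),
        replica=per_frame["replica"].to_numpy() if "replica" in df else None,
        time_ps=per_frame["time_ps"].to_numpy() if "time_ps" in df else None,
    )


# ---------------------------------------------------------------------------
# Superposition and fluctuation primitives
# ---------------------------------------------------------------------------

def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid (Kabsch) fit of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` optimally matches ``reference``
    over ``selection`` (all atoms when None). Only proper rotations are
    considered; the RMSD is the unweighted post-fit RMSD over the selection.
    """
    mob = np.asarray(mobile, dtype=float).reshape(-1, 3)
    ref = np.asarray(reference, dtype=float).reshape(-1, 3)
    if selection is None:
        selection = np.arange(len(mob))
    selection = np.asarray(selection, dtype=int)
    if selection.size < 1:
        raise ValueError("selection must contain at least one atom")
    a = ref[selection]
    b = mob[selection]
    a_c = a.mean(axis=0)
    b_c = b.mean(axis=0)
    if selection.size == 1:
        rot = np.eye(3)
    else:
        r, _ = Rotation.align_vectors(a - a_c, b - b_c)
        rot = r.as_matrix()
    trans = a_c - rot @ b_c
    fitted = b @ rot.T + trans
    out = float(np.sqrt(np.mean(np.sum((fitted - a) ** 2, axis=1))))
    return rot, trans, out


def rmsd(a: np.ndarray, b: np.ndarray, selection: np.ndarray | None = None) -> float:
    """Minimum RMSD between two conformations after optimal superposition."""
    return superpose(a, b, selection)[2]


def apply_transform(coords: np.ndarray, rot: np.ndarray, trans: np.ndarray) -> np.ndarray:
    return (np.asarray(coords, float).reshape(-1, 3) @ rot.T + trans).ravel()


def rmsd_series(
    ensemble: Ensemble,
    reference: Structure | np.ndarray,
    selection: np.ndarray,
    fit_selection: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame RMSD to a reference after fitting on ``fit_selection``.

    Each frame is superposed on the reference over ``fit_selection`` (defaults
    to ``selection``), then the unweighted RMSD is measured over ``selection``.
    """
    ref = reference.coords if isinstance(reference, Structure) else reference
    ref_xyz = np.asarray(ref, dtype=float).reshape(-1, 3)
    if fit_selection is None:
        fit_selection = selection
    out = np.empty(ensemble.n_frames)
    for k in range(ensemble.n_frames):
        rot, trans, _ = superpose(ensemble.frames[k], ref_xyz, fit_selection)
        fitted = apply_transform(ensemble.frames[k], rot, trans).reshape(-1, 3)
        d = fitted[selection] - ref_xyz[selection]
        out[k] = np.sqrt(np.mean(np.sum(d * d, axis=1)))
    return out


def rmsf(
    ensemble: Ensemble,
    selection: np.ndarray | None = None,
    max_iter: int = 10,
    tol: float = 1e-6,
) -> np.ndarray:
    """Per-atom RMS fluctuation about the iteratively fitted mean structure.

    Frames are superposed to their running mean (at most ``max_iter``
    refinement passes, stopping when the mean shifts by < ``tol`` Å RMS),
    then RMSF_i = sqrt(<|r_i - <r_i>|^2>) is returned for the selected atoms.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF undefined for fewer than 2 frames")
    n_atoms = ensemble.frames.shape[1] // 3
    if selection is None:
        selection = np.arange(n_atoms)
    selection = np.asarray(selection, dtype=int)
    fitted = ensemble.frames.copy()
    mean = fitted[0].copy()
    for _ in range(max_iter):
        for k in range(fitted.shape[0]):
            rot, trans, _ = superpose(fitted[k], mean, selection)
            fitted[k] = apply_transform(fitted[k], rot, trans)
        new_mean = fitted.mean(axis=0)
        shift = np.sqrt(np.mean((new_mean - mean) ** 2))
        mean = new_mean
        if shift < tol:
            break
    dev = fitted.reshape(fitted.shape[0], n_atoms, 3) - mean.reshape(n_atoms, 3)
    msf = np.mean(np.sum(dev * dev, axis=2), axis=0)
    return np.sqrt(msf[selection])
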