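"""Core data model: topology, frames, trajectories, periodic boxes, and the
bilayer-centric geometry primitives (centering and leaflet assignment) that
every downstream metric builds on.

Conventions
-----------
* All coordinates and box lengths are in nanometres.  PDB files (which store
  angstroms) are converted on read.
* The membrane normal is the z axis.  After :func:`center_on_bilayer` the
  bilayer midplane sits at z = 0, so the upper leaflet is z > 0 and the lower
  leaflet z < 0.
* Boxes are rectangular.  In-plane (x, y) distances always use the
  minimum-image convention; z is treated as non-periodic for leaflet and
  depth logic (the bilayer is bounded in z) but periodically for contact and
  energy distances, where molecules may straddle the box wall.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COULOMB_CONSTANT",
    "MoleculeKind",
    "LipidGroup",
    "Leaflet",
    "Atom",
    "System",
    "Frame",
    "Trajectory",
    "TimeWindow",
    "LeafletAssignment",
    "ParameterTableError",
    "read_parameter_table",
    "write_parameter_table",
    "load_system",
    "load_trajectory",
    "min_image_displacement",
    "min_image_distance",
    "bilayer_center",
    "center_on_bilayer",
    "assign_leaflets",
    "validate_whole_molecules",
]

#: Electric conversion factor f = 1/(4 pi eps0) in kJ mol^-1 nm e^-2.
COULOMB_CONSTANT = 138.935485

PARAMETER_COLUMNS = [
    "residue_name",
    "atom_name",
    "element",
    "charge",
    "c6",
    "c12",
    "molecule_kind",
    "lipid_group",
]


class MoleculeKind(str, Enum):
    PEPTIDE = "peptide"
    LIPID = "lipid"
    WATER = "water"
    ION = "ion"


class LipidGroup(str, Enum):
    HEAD = "head"
    TAIL = "tail"
    NONE = "none"


class Leaflet(str, Enum):
    UPPER = "upper"
    LOWER = "lower"


class ParameterTableError(ValueError):
    """A coordinate atom has no row in the per-atom parameter table."""


@dataclass(frozen=True)
class Atom:
    """Single-atom view onto a :class:`System` (columnar storage underneath)."""

    index: int
    name: str
    element: str
    is_hydrogen: bool
    residue_index: int
    residue_name: str
    chain_id: str
    molecule_kind: MoleculeKind
    charge: float
    lj_c6: float
    lj_c12: float
    lipid_group: LipidGroup


@dataclass
class System:
    """Topology of one molecular system: atoms grouped into residues, chains
    and molecules, carrying partial charges, Lennard-Jones C6/C12 parameters
    and the lipid head/tail partition.

    Arrays are aligned per atom, in coordinate-file order.
    """

    names: np.ndarray
    elements: np.ndarray
    residue_index: np.ndarray  # 0-based, global
    residue_name: np.ndarray
    chain_id: np.ndarray
    molecule_kind: np.ndarray  # str values of MoleculeKind
    molecule_index: np.ndarray  # 0-based, global molecule id
    charge: np.ndarray
    c6: np.ndarray
    c12: np.ndarray
    lipid_group: np.ndarray  # str values of LipidGroup

    def __post_init__(self) -> None:
        n = len(self.names)
        for fname in ("elements", "residue_index", "residue_name", "chain_id",
                      "molecule_kind", "molecule_index", "charge", "c6",
                      "c12", "lipid_group"):
            if len(getattr(self, fname)) != n:
                raise ValueError(f"field {fname!r} has wrong length")
        if not np.all(np.isfinite(self.charge)):
            raise ValueError("charges must be finite")
        if np.any(self.c6 < 0) or np.any(self.c12 < 0):
            raise ValueError("Lennard-Jones C6/C12 must be non-negative")
        bad = (self.molecule_kind != MoleculeKind.LIPID.value) & (
            self.lipid_group != LipidGroup.NONE.value)
        if np.any(bad):
            raise ValueError("lipid_group must be 'none' for non-lipid atoms")

    # ------------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def is_hydrogen(self) -> np.ndarray:
        return self.elements == "H"

    @property
    def heavy_mask(self) -> np.ndarray:
        return self.elements != "H"

    @property
    def phosphorus_mask(self) -> np.ndarray:
        return (self.elements == "P") & (
            self.molecule_kind == MoleculeKind.LIPID.value)

    def atom(self, i: int) -> Atom:
        return Atom(
            index=i,
            name=str(self.names[i]),
            element=str(self.elements[i]),
            is_hydrogen=str(self.elements[i]) == "H",
            residue_index=int(self.residue_index[i]),
            residue_name=str(self.residue_name[i]),
            chain_id=str(self.chain_id[i]),
            molecule_kind=MoleculeKind(str(self.molecule_kind[i])),
            charge=float(self.charge[i]),
            lj_c6=float(self.c6[i]),
            lj_c12=float(self.c12[i]),
            lipid_group=LipidGroup(str(self.lipid_group[i])),
        )

    # -- derived groupings ---------------------------------------------
    def lipid_molecules(self) -> list[np.ndarray]:
        """Atom-index arrays, one per lipid molecule, in molecule order."""
        mask = self.molecule_kind == MoleculeKind.LIPID.value
        ids = np.unique(self.molecule_index[mask])
        return [np.flatnonzero(mask & (self.molecule_index == m)) for m in ids]

    def lipid_phosphorus_indices(self) -> np.ndarray:
        """One phosphorus atom index per lipid; errors if a lipid has none."""
        out = []
        for atoms in self.lipid_molecules():
            p = atoms[self.elements[atoms] == "P"]
            if p.size == 0:
                resname = self.residue_name[atoms[0]]
                raise ValueError(
                    f"lipid molecule {self.molecule_index[atoms[0]]} "
                    f"({resname}) has no phosphorus atom")
            out.append(p[0])
        return np.asarray(out, dtype=int)

    def peptide_chain_ids(self) -> list[str]:
        mask = self.molecule_kind == MoleculeKind.PEPTIDE.value
        ids: list[str] = []
        for c in self.chain_id[mask]:
            if c not in ids:
                ids.append(str(c))
        return ids

    def chain_atoms(self, chain: str) -> np.ndarray:
        idx = np.flatnonzero(
            (self.chain_id == chain)
            & (self.molecule_kind == MoleculeKind.PEPTIDE.value))
        if idx.size == 0:
            raise KeyError(f"no peptide chain with id {chain!r}")
        return idx

    def chain_residues(self, chain: str) -> list[np.ndarray]:
        """Atom-index arrays per residue of one peptide chain, N→C order."""
        atoms = self.chain_atoms(chain)
        resids = self.residue_index[atoms]
        out = []
        for r in np.unique(resids):
            out.append(atoms[resids == r])
        return out

    def equal(self, other: "System") -> bool:
        if self.n_atoms != other.n_atoms:
            return False
        str_fields = ("names", "elements", "residue_name", "chain_id",
                      "molecule_kind", "lipid_group")
        int_fields = ("residue_index", "molecule_index")
        for f_ in str_fields + int_fields:
            if not np.array_equal(getattr(self, f_), getattr(other, f_)):
                return False
        for f_ in ("charge", "c6", "c12"):
            if not np.allclose(getattr(self, f_), getattr(other, f_),
                               rtol=0, atol=1e-12):
                return False
        return True


@dataclass
class Frame:
    """One trajectory frame: time (ns), coordinates (nm) and box (nm)."""

    time: float
    coordinates: np.ndarray  # (n_atoms, 3)
    box: np.ndarray  # (3,) rectangular box lengths

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")

    def shifted_z(self, dz: float) -> "Frame":
        coords = self.coordinates.copy()
        coords[:, 2] += dz
        return Frame(time=self.time, coordinates=coords, box=self.box.copy())


@dataclass
class Trajectory:
    """Ordered frames sharing one topology."""

    frames: list[Frame]
    topology: System

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory needs at least one frame")
        times = np.array([f.time for f in self.frames])
        if np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        n = self.topology.n_atoms
        for f in self.frames:
            if f.coordinates.shape[0] != n:
                raise ValueError("frame atom count does not match topology")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


@dataclass(frozen=True)
class TimeWindow:
    """Half-open-on-neither-side averaging window [t_start, t_end] in ns."""

    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("need t_start < t_end")

    def select(self, traj: Trajectory) -> list[int]:
        idx = [i for i, f in enumerate(traj.frames)
               if self.t_start <= f.time <= self.t_end]
        if not idx:
            raise ValueError(
                f"window [{self.t_start}, {self.t_end}] ns selects no frame")
        return idx

    @staticmethod
    def last(traj: Trajectory, duration: float) -> "TimeWindow":
        """The trailing *duration* ns of a trajectory."""
        t_end = traj.frames[-1].time
        return TimeWindow(t_start=t_end - duration, t_end=t_end)


@dataclass
class LeafletAssignment:
    """Per-lipid upper/lower label for one frame."""

    labels: np.ndarray  # str values of Leaflet, one per lipid molecule
    time: float

    @property
    def upper(self) -> np.ndarray:
        return np.flatnonzero(self.labels == Leaflet.UPPER.value)

    @property
    def lower(self) -> np.ndarray:
        return np.flatnonzero(self.labels == Leaflet.LOWER.value)

    def of(self, leaflet: Leaflet | str) -> np.ndarray:
        leaflet = Leaflet(leaflet)
        return self.upper if leaflet is Leaflet.UPPER else self.lower


# ---------------------------------------------------------------------------
# Periodic geometry
# ---------------------------------------------------------------------------

def min_image_displacement(delta: np.ndarray, box: np.ndarray,
                           dims: Sequence[int] = (0, 1, 2)) -> np.ndarray:
    """Wrap displacement vectors to the nearest periodic image.

    Only the axes in *dims* are wrapped; a rectangular box is assumed.
    """
    delta = np.array(delta, dtype=float, copy=True)
    for d in dims:
        delta[..., d] -= box[d] * np.round(delta[..., d] / box[d])
    return delta


def min_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray,
                       dims: Sequence[int] = (0, 1, 2)) -> np.ndarray:
    """Pairwise minimum-image distances between point sets a (n,3), b (m,3)."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    delta = a[:, None, :] - b[None, :, :]
    delta = min_image_displacement(delta, box, dims)
    return np.sqrt(np.sum(delta * delta, axis=-1))


# ---------------------------------------------------------------------------
# Parameter table I/O
# ---------------------------------------------------------------------------

def read_parameter_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read the whitespace-delimited per-atom parameter table.

    Columns: ``residue_name atom_name element charge c6 c12 molecule_kind
    lipid_group``; one row per (residue_name, atom_name) pair.
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    missing = [c for c in PARAMETER_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterTableError(
            f"parameter table {path} lacks columns: {missing}")
    for col in ("molecule_kind",):
        bad = set(df[col]) - {k.value for k in MoleculeKind}
        if bad:
            raise ParameterTableError(f"unknown molecule_kind values: {bad}")
    bad = set(df["lipid_group"]) - {g.value for g in LipidGroup}
    if bad:
        raise ParameterTableError(f"unknown lipid_group values: {bad}")
    return df


def write_parameter_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep=" ", index=False)


# ---------------------------------------------------------------------------
# Coordinate / trajectory readers (mdtraj backend)
# ---------------------------------------------------------------------------

def _load_mdtraj(coords_path, top_path=None):
    import mdtraj as md

    ext = os.path.splitext(str(coords_path))[1].lower()
    if ext in (".xtc", ".dcd", ".trr"):
        if top_path is None:
            raise ValueError(
                f"binary trajectory {coords_path} needs a topology file")
        return md.load(str(coords_path), top=str(top_path))
    try:
        return md.load(str(coords_path))
    except Exception as exc:  # mdtraj raises assorted parse errors
        raise ValueError(f"could not parse {coords_path}: {exc}") from exc


def _assign_chains(resnames: np.ndarray, resseq: np.ndarray,
                   kinds: np.ndarray, res_first_atom: np.ndarray) -> np.ndarray:
    """Chain id per residue.  Peptide chains are consecutive runs of peptide
    residues with increasing residue numbers; a restart or gap > 1 starts a
    new chain, labelled A, B, ...  Non-peptide residues get ''."""
    n_res = len(resnames)
    chains = np.empty(n_res, dtype=object)
    chains[:] = ""
    letter = 0
    prev_seq = None
    prev_was_pep = False
    for r in range(n_res):
        if kinds[r] == MoleculeKind.PEPTIDE.value:
            if not prev_was_pep or resseq[r] != prev_seq + 1:
                label = chr(ord("A") + letter)
                letter += 1
            chains[r] = label
            prev_seq = resseq[r]
            prev_was_pep = True
        else:
            prev_was_pep = False
    return chains


def load_system(coords_path: str | os.PathLike,
                params_path: str | os.PathLike) -> System:
    """Build a :class:`System` from a coordinate file plus parameter table.

    The coordinate file (PDB or GRO) fixes the atom order; the table supplies
    charges, C6/C12, molecule kind and the lipid head/tail label per
    (residue_name, atom_name).  Every atom must be covered — a missing row is
    a hard error naming the first offending atom.
    """
    t = _load_mdtraj(coords_path)
    top = t.topology
    params = read_parameter_table(params_path)
    lut = {(str(r.residue_name), str(r.atom_name)): r
           for r in params.itertuples(index=False)}

    n = top.n_atoms
    names = np.empty(n, dtype=object)
    elements = np.empty(n, dtype=object)
    resname = np.empty(n, dtype=object)
    res_idx = np.empty(n, dtype=int)
    charge = np.empty(n)
    c6 = np.empty(n)
    c12 = np.empty(n)
    kind = np.empty(n, dtype=object)
    group = np.empty(n, dtype=object)

    residues = list(top.residues)
    res_kinds = np.empty(len(residues), dtype=object)
    res_seq = np.array([r.resSeq for r in residues])

    for a in top.atoms:
        i = a.index
        rn, an = a.residue.name, a.name
        row = lut.get((rn, an))
        if row is None:
            raise ParameterTableError(
                f"no parameters for atom {an!r} of residue {rn!r} "
                f"(atom index {i})")
        names[i] = an
        resname[i] = rn
        res_idx[i] = a.residue.index
        elements[i] = str(row.element)
        charge[i] = float(row.charge)
        c6[i] = float(row.c6)
        c12[i] = float(row.c12)
        kind[i] = str(row.molecule_kind)
        group[i] = str(row.lipid_group)
        res_kinds[a.residue.index] = str(row.molecule_kind)

    res_chain = _assign_chains(
        np.array([r.name for r in residues], dtype=object),
        res_seq, res_kinds,
        np.array([r.atom(0).index for r in residues]))
    chain_id = res_chain[res_idx].astype(object)

    # molecules: each peptide chain is one molecule; every other residue is
    # its own molecule (lipid, water, ion)
    mol_idx = np.empty(n, dtype=int)
    mol = -1
    seen_chain: dict[str, int] = {}
    for r, residue in enumerate(residues):
        if res_kinds[r] == MoleculeKind.PEPTIDE.value:
            cid = res_chain[r]
            if cid not in seen_chain:
                mol += 1
                seen_chain[cid] = mol
            m = seen_chain[cid]
        else:
            mol += 1
            m = mol
        for a in residue.atoms:
            mol_idx[a.index] = m

    return System(names=names, elements=elements, residue_index=res_idx,
                  residue_name=resname, chain_id=chain_id,
                  molecule_kind=kind, molecule_index=mol_idx,
                  charge=charge, c6=c6, c12=c12, lipid_group=group)


def load_trajectory(coords_path: str | os.PathLike,
                    params_path: str | os.PathLike,
                    traj_path: str | os.PathLike | None = None,
                    validate: bool = True) -> Trajectory:
    """Load a trajectory: multi-frame PDB/GRO, or XTC/DCD/TRR plus topology.

    If *traj_path* is None the coordinate file itself supplies the frames.
    Times are taken from the file where present (ps converted to ns for
    mdtraj-backed formats); otherwise frames are numbered 0, 1, 2, ... ns.
    """
    system = load_system(coords_path, params_path)
    t = _load_mdtraj(traj_path if traj_path is not None else coords_path,
                     top_path=coords_path)
    if t.unitcell_lengths is None:
        raise ValueError(f"{coords_path}: no box information")
    times = np.asarray(t.time, dtype=float) / 1000.0  # mdtraj ps -> ns
    if len(times) == 0 or np.any(np.diff(times) <= 0):
        times = np.arange(t.n_frames, dtype=float)
    frames = [Frame(time=times[i],
                    coordinates=np.asarray(t.xyz[i], dtype=float),
                    box=np.asarray(t.unitcell_lengths[i], dtype=float))
              for i in range(t.n_frames)]
    traj = Trajectory(frames=frames, topology=system)
    if validate:
        for i, fr in enumerate(traj.frames):
            validate_whole_molecules(fr, system, frame_label=str(i))
    return traj


def validate_whole_molecules(frame: Frame, system: System,
                             frame_label: str = "") -> None:
    """Reject frames with broken (wrapped) molecules.

    Heuristic: within each molecule, consecutive atoms in file order must be
    closer than half the smallest box length (no bond topology is inferred).
    """
    limit = 0.5 * float(np.min(frame.box))
    for m in np.unique(system.molecule_index):
        idx = np.flatnonzero(system.molecule_index == m)
        if idx.size < 2:
            continue
        xyz = frame.coordinates[idx]
        step = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        if np.any(step > limit):
            raise ValueError(
                f"molecule {m} appears wrapped across the periodic boundary "
                f"(frame {frame_label}): consecutive-atom distance "
                f"{step.max():.3f} nm exceeds {limit:.3f} nm")


# ---------------------------------------------------------------------------
# Bilayer centering and leaflet assignment
# ---------------------------------------------------------------------------

def _phosphorus_z(frame: Frame, system: System) -> np.ndarray:
    p = system.lipid_phosphorus_indices()
    if p.size < 2:
        raise ValueError("need at least two lipids with phosphorus atoms")
    return frame.coordinates[p, 2]


def bilayer_center(frame: Frame, system: System) -> float:
    """z of the bilayer midplane: midpoint between the mean phosphorus z of
    the two leaflets.

    The leaflet split is bootstrapped about the median phosphorus z, then the
    midpoint-of-means is iterated once — robust to unequal leaflet
    populations, and independent of any prior centering.
    """
    z = _phosphorus_z(frame, system)
    center = float(np.median(z))
    for _ in range(2):
        upper = z > center
        if not upper.any() or upper.all():
            raise ValueError("cannot split phosphorus atoms into two leaflets")
        center = 0.5 * (z[upper].mean() + z[~upper].mean())
    return center


def center_on_bilayer(frame: Frame, system: System) -> Frame:
    """Shift a frame in z so the bilayer midplane sits at z = 0."""
    return frame.shifted_z(-bilayer_center(frame, system))


def assign_leaflets(frame: Frame, system: System,
                    centered: bool = False) -> LeafletAssignment:
    """Label each lipid upper (phosphorus z > 0) or lower (z < 0).

    The frame is centered internally unless *centered* says it already is,
    so the assignment is invariant under whole-frame translations.
    """
    if not centered:
        frame = center_on_bilayer(frame, system)
    z = _phosphorus_z(frame, system)
    labels = np.where(z > 0, Leaflet.UPPER.value, Leaflet.LOWER.value)
    return LeafletAssignment(labels=labels.astype(object), time=frame.time)
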