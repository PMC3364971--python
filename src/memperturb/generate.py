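"""Synthetic bilayer + peptide trajectory generator with planted ground truth.

Every downstream metric in this package (insertion depth, leaflet labels,
head-group z-displacement, thickness maps, S_CD order parameters, contacts,
energies, secondary structure) can be validated against analytically known
values planted here:

* Lipids sit on a jittered rectangular lattice, one phosphorus head-group
  atom per lipid at z = ±leaflet_z (the upper plane optionally deformed by a
  Gaussian dimple) and an ordered acyl chain descending toward the midplane
  whose C-H vectors make a prescribed angle with the membrane normal, so the
  deuterium order parameter of every carbon is exactly 0.5(3cos²θ₀ − 1).
* Peptides are ideal α-helices (φ = −57°, ψ = −47°) at prescribed tilt,
  insertion depth and inter-chain separation, with charged side-chain
  pseudo-atoms on the lysine/arginine positions.
* Frames are independent identically-distributed copies: each molecule gets
  an independent rigid Gaussian displacement per frame.  All the metrics this
  package computes are time averages of static observables, so no integrator
  is needed; rigid per-molecule jitter emulates thermal positional disorder
  (e.g. lipid protrusion) while preserving internal geometry exactly.

The generator emulates an anionic single-chain lipid bilayer of 2x64 lipids
in a 5 x 7 x 9 nm box with phosphate planes near ±2.2 nm, and one or two
37-residue amphipathic peptides whose charge (+1 side chain on residues 1
and 11, +1 N-terminal amine) mirrors an amylin-like peptide at neutral pH.
No water or ions are generated: the energy decomposition treats only
peptide-lipid pairs.  Sterics are not relaxed, so van der Waals magnitudes
on peptide-containing systems are not physical; electrostatic structure is.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .system import (
    Frame,
    Leaflet,
    LipidGroup,
    MoleculeKind,
    System,
    Trajectory,
    min_image_displacement,
    write_parameter_table,
)

__all__ = [
    "HIAPP_SEQUENCE",
    "Dimple",
    "GeneratorParams",
    "GroundTruth",
    "PeptideStructure",
    "ideal_helix",
    "generate_system",
    "write_files",
    "preset",
    "PRESET_NAMES",
]

#: 37-residue amylin (hIAPP) sequence; K1 and R11 carry the charges.
HIAPP_SEQUENCE = "KCNTATCATQRLANFLVHSSNNFGAILSSTNVGSNTY"

_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}

# generic Lennard-Jones parameters (kJ mol^-1 nm^6 / nm^12): one carbon-like
# set for peptide heavy atoms and tail carbons, a larger set for phosphorus
_LJ_C = (4.0e-3, 4.0e-6)
_LJ_P = (8.0e-3, 2.0e-5)

_HELICAL = (-57.0, -47.0)
_EXTENDED = (180.0, 180.0)


# ---------------------------------------------------------------------------
# Internal-coordinate chain building (NeRF)
# ---------------------------------------------------------------------------

def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Place atom d given reference atoms a-b-c, the c-d bond length, the
    b-c-d angle and the a-b-c-d dihedral (degrees; lengths in the caller's
    unit)."""
    theta = math.radians(angle)
    phi = math.radians(dihedral)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * math.cos(theta),
                  bond * math.sin(theta) * math.cos(phi),
                  bond * math.sin(theta) * math.sin(phi)])
    return c + d[0] * bc + d[1] * m + d[2] * n


@dataclass
class PeptideStructure:
    """A built peptide: coordinates in nm plus per-atom metadata."""

    coordinates: np.ndarray  # (n_atoms, 3)
    names: list[str]
    residue_numbers: list[int]  # 1-based
    residue_names: list[str]
    sequence: str
    helix_window: tuple[int, int]  # 1-based inclusive, residues built helical

    @property
    def n_residues(self) -> int:
        return max(self.residue_numbers)

    def residue_atom_indices(self, resnum: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.residue_numbers) == resnum)

    def planted_helix_residues(self) -> list[int]:
        """Residues expected helical by hydrogen-bond based assignment: the
        helical-dihedral window clipped at the chain termini (the first and
        last chain residues cannot carry the flanking i→i+4 bond pattern)."""
        a, b = self.helix_window
        return list(range(max(a, 2), min(b, self.n_residues - 1) + 1))


def ideal_helix(n_residues: int,
                helix_window: tuple[int, int] | None = None,
                sequence: str | None = None) -> PeptideStructure:
    """Build a peptide with backbone N, CA, C, O per residue and a charged
    side-chain pseudo-atom (CB) on the lysine/arginine positions.

    Residues inside *helix_window* (1-based inclusive; default: all) get
    canonical α-helical dihedrals φ = −57°, ψ = −47° (rise ≈ 0.15 nm per
    residue, consecutive CA-CA ≈ 0.38 nm); the rest are built extended
    (φ = ψ = 180°).  With the default 37-residue length the amylin sequence
    is used, so residue 1 is LYS and residue 11 ARG; other lengths get a
    poly-alanine with LYS/ARG substituted at positions 1 and 11.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues to define a helix")
    if sequence is None:
        if n_residues == len(HIAPP_SEQUENCE):
            sequence = HIAPP_SEQUENCE
        else:
            seq = ["A"] * n_residues
            seq[0] = "K"
            if n_residues >= 11:
                seq[10] = "R"
            sequence = "".join(seq)
    if len(sequence) != n_residues:
        raise ValueError("sequence length does not match n_residues")
    if helix_window is None:
        helix_window = (1, n_residues)
    a0, b0 = helix_window
    if not (1 <= a0 < b0 <= n_residues):
        raise ValueError("helix_window must be within the chain")

    phi = np.empty(n_residues)
    psi = np.empty(n_residues)
    for r in range(n_residues):
        ang = _HELICAL if a0 - 1 <= r <= b0 - 1 else _EXTENDED
        phi[r], psi[r] = ang

    coords: list[np.ndarray] = []  # in angstrom while building
    names: list[str] = []
    resnum: list[int] = []
    resname: list[str] = []

    def add(name, r, xyz):
        names.append(name)
        resnum.append(r + 1)
        resname.append(_AA3[sequence[r]])
        coords.append(np.asarray(xyz, dtype=float))

    # residue 0 seed
    n_at = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    c = ca + 1.525 * np.array([-math.cos(math.radians(111.2)),
                               math.sin(math.radians(111.2)), 0.0])
    prev = {"N": n_at, "CA": ca, "C": c}
    for r in range(n_residues):
        if r > 0:
            n_at = _nerf(prev["N"], prev["CA"], prev["C"],
                         1.329, 116.2, psi[r - 1])
            ca = _nerf(prev["CA"], prev["C"], n_at, 1.458, 121.7, 180.0)
            c = _nerf(prev["C"], n_at, ca, 1.525, 111.2, phi[r])
        o = _nerf(n_at, ca, c, 1.231, 120.8, psi[r] + 180.0)
        add("N", r, n_at)
        add("CA", r, ca)
        add("C", r, c)
        add("O", r, o)
        if _AA3[sequence[r]] in ("LYS", "ARG"):
            cb = _nerf(n_at, c, ca, 1.53, 110.1, -122.6)
            add("CB", r, cb)
        prev = {"N": n_at, "CA": ca, "C": c}

    xyz = np.array(coords) / 10.0  # angstrom -> nm
    return PeptideStructure(coordinates=xyz, names=names,
                            residue_numbers=resnum, residue_names=resname,
                            sequence=sequence, helix_window=helix_window)


# ---------------------------------------------------------------------------
# Generator parameters and ground truth
# ---------------------------------------------------------------------------

@dataclass
class Dimple:
    """Gaussian depression of the upper phosphate plane: lipids within the
    dimple footprint are shifted down by amplitude·exp(−r²/2 width²)."""

    amplitude: float  # nm
    width: float  # nm (Gaussian sigma)
    center: tuple[float, float]  # x, y in nm

    def depth_at(self, x, y) -> np.ndarray:
        dx = np.asarray(x) - self.center[0]
        dy = np.asarray(y) - self.center[1]
        return self.amplitude * np.exp(-(dx ** 2 + dy ** 2)
                                       / (2.0 * self.width ** 2))


@dataclass
class GeneratorParams:
    """Study conditions for one synthetic system.

    Defaults emulate the reference setup: 2x64 anionic lipids in a
    5 x 7 x 9 nm box, phosphate planes at ±2.2 nm, a 16-carbon ordered acyl
    chain per lipid, and a 37-residue helical peptide lying nearly in-plane
    with its N-terminal end inserted below the upper phosphate plane.
    ``tail_tilt_theta`` is the exact C-H angle to the membrane normal; the
    default 63.435° plants S_CD = −0.2 per carbon, a typical fluid-chain
    magnitude.  ``peptide_tilt``/``peptide_depth`` accept one value per
    chain.  ``jitter_sigma`` is the per-molecule rigid displacement noise
    (nm, per coordinate, independent per frame).
    """

    n_lipids_per_leaflet: int = 64
    leaflet_z: float = 2.2
    tail_carbons: int = 16
    tail_tilt_theta: float = 63.434949
    jitter_sigma: float = 0.05
    box: tuple[float, float, float] = (5.0, 7.0, 9.0)
    n_peptides: int = 1
    peptide_length: int = 37
    peptide_tilt: float | tuple[float, ...] = 10.0
    peptide_depth: float | tuple[float, ...] = 1.5
    interchain_min_distance: float = 0.25
    dimer_contact: bool = False
    dimple: Dimple | None = None
    seed: int = 0
    n_frames: int = 51
    frame_dt: float = 3.0  # ns
    explicit_hydrogens: bool = True
    helix_window: tuple[int, int] | None = None
    center_offset: float = 0.0  # lab-frame z shift of the whole system

    def __post_init__(self) -> None:
        if self.n_peptides not in (0, 1, 2):
            raise ValueError("n_peptides must be 0, 1 or 2")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        for v in (self.leaflet_z, *self.box):
            if v <= 0:
                raise ValueError("lengths must be positive")

    def per_chain(self, value) -> list[float]:
        if isinstance(value, (tuple, list)):
            if len(value) != self.n_peptides:
                raise ValueError("need one value per peptide chain")
            return [float(v) for v in value]
        return [float(value)] * self.n_peptides


@dataclass
class GroundTruth:
    """Exact planted values for every metric, emitted alongside the system."""

    leaflet_labels: list[str]
    thickness_grid_origin: tuple[float, float]
    thickness_grid_spacing: tuple[float, float]
    thickness_smoothing_radius: float
    thickness_field: np.ndarray  # (nx, ny), nm
    scd_per_carbon: list[float]
    scd_value: float
    contact_counts: dict[str, int] | None
    min_interchain_distance: float | None
    helix_residues: dict[str, list[int]]
    per_residue_min_z: dict[str, list[float]]
    bilayer_center_offset: float
    n_lipids: int

    def to_json(self, path: str | os.PathLike) -> None:
        d = asdict(self)
        d["thickness_field"] = np.asarray(self.thickness_field).tolist()
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @staticmethod
    def from_json(path: str | os.PathLike) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["thickness_field"] = np.asarray(d["thickness_field"])
        if d["contact_counts"] is not None:
            d["contact_counts"] = dict(d["contact_counts"])
        return GroundTruth(**d)


# ---------------------------------------------------------------------------
# Lipid template
# ---------------------------------------------------------------------------

def _lipid_template(params: GeneratorParams, upper: bool,
                    azimuth: float) -> tuple[np.ndarray, list[str]]:
    """Local coordinates (relative to the head phosphorus at the origin) and
    atom names of one lipid.

    Explicit-hydrogen mode: carbons stack straight toward the midplane and
    each carries two hydrogens whose C-H unit vectors make exactly
    ``tail_tilt_theta`` with +z (mirror pair about the chain axis, rotated by
    the lipid's azimuth).  United-atom mode: no hydrogens; the chain is an
    all-trans zigzag tilted so that the standard tetrahedral H-reconstruction
    yields the same planted order parameter (requires cos²θ₀ ≤ 1/3, i.e.
    54.7° ≤ θ₀ ≤ 125.3°).
    """
    nc = params.tail_carbons
    theta0 = math.radians(params.tail_tilt_theta)
    sgn = 1.0 if upper else -1.0  # +z is "out of the membrane" for upper
    ca, sa = math.cos(azimuth), math.sin(azimuth)

    def rot_z(v):
        return np.array([ca * v[0] - sa * v[1], sa * v[0] + ca * v[1], v[2]])

    coords = [np.zeros(3)]  # P at origin
    names = ["P"]
    if params.explicit_hydrogens:
        dz = 0.125
        ch = 0.109  # C-H bond length, nm
        u1 = rot_z(np.array([math.sin(theta0), 0.0, math.cos(theta0)]))
        u2 = rot_z(np.array([-math.sin(theta0), 0.0, math.cos(theta0)]))
        if not upper:
            u1 = u1 * np.array([1.0, 1.0, -1.0])
            u2 = u2 * np.array([1.0, 1.0, -1.0])
        for k in range(nc):
            c = np.array([0.0, 0.0, sgn * (-0.15 - k * dz)])
            coords += [c, c + ch * u1, c + ch * u2]
            names += [f"C{k + 1}", f"H{k + 1}A", f"H{k + 1}B"]
    else:
        cos2 = math.cos(theta0) ** 2
        if 3.0 * cos2 > 1.0 + 1e-12:
            raise ValueError(
                "united-atom mode supports tail_tilt_theta in "
                "[54.74°, 125.26°] only (tetrahedral reconstruction)")
        alpha = math.acos(math.sqrt(max(0.0, 1.0 - 3.0 * cos2)))
        bond = 0.153
        half = math.radians(111.0) / 2.0
        s = bond * math.sin(half)  # axial step per carbon
        h = 0.5 * bond * math.cos(half)  # lateral zigzag half-offset
        axis = rot_z(np.array([math.sin(alpha), 0.0, -math.cos(alpha)]))
        perp = rot_z(np.array([math.cos(alpha), 0.0, math.sin(alpha)]))
        if not upper:
            axis = axis * np.array([1.0, 1.0, -1.0])
            perp = perp * np.array([1.0, 1.0, -1.0])
        r0 = np.array([0.0, 0.0, sgn * -0.15])
        for k in range(nc):
            c = r0 + k * s * axis + ((-1) ** k) * h * perp
            coords.append(c)
            names.append(f"C{k + 1}")
    return np.array(coords), names


def _lattice(n: int, lx: float, ly: float) -> np.ndarray:
    """n sites on a near-square rectangular lattice filling lx × ly."""
    best = None
    for nx in range(1, n + 1):
        if n % nx:
            continue
        ny = n // nx
        cost = abs(lx / nx - ly / ny)
        if best is None or cost < best[0]:
            best = (cost, nx, ny)
    _, nx, ny = best
    sx, sy = lx / nx, ly / ny
    pts = [((i + 0.5) * sx, (j + 0.5) * sy)
           for j in range(ny) for i in range(nx)]
    return np.array(pts)


# ---------------------------------------------------------------------------
# Peptide placement
# ---------------------------------------------------------------------------

def _principal_axis(ca: np.ndarray) -> np.ndarray:
    c = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    return axis


def _rot_align_x(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix taking *axis* to +x."""
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(axis, x)
    s = np.linalg.norm(v)
    c = float(np.dot(axis, x))
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)


def _rot_y(deg: float) -> np.ndarray:
    t = math.radians(deg)
    return np.array([[math.cos(t), 0, math.sin(t)], [0, 1, 0],
                     [-math.sin(t), 0, math.cos(t)]])


def _rot_z_mat(deg: float) -> np.ndarray:
    t = math.radians(deg)
    return np.array([[math.cos(t), -math.sin(t), 0],
                     [math.sin(t), math.cos(t), 0], [0, 0, 1]])


def _place_peptide(pep: PeptideStructure, tilt: float, depth: float,
                   xy: tuple[float, float], z_ref: float,
                   v_angle: float = 0.0) -> np.ndarray:
    """Rigidly place a built peptide: helix axis along +x (N-terminus at low
    x), tilted about y so the N-terminal end dips, rotated by *v_angle*
    about z, then translated so its lowest atom sits at z_ref + depth and
    its axis midpoint at *xy*."""
    xyz = pep.coordinates.copy()
    ca = xyz[[i for i, n in enumerate(pep.names) if n == "CA"]]
    r = _rot_align_x(_principal_axis(ca))
    xyz = xyz @ r.T
    xyz = xyz @ _rot_y(-tilt).T  # N-terminal (low-x) end goes down
    xyz = xyz @ _rot_z_mat(v_angle).T
    mid = 0.5 * (xyz.min(axis=0) + xyz.max(axis=0))
    xyz[:, 0] += xy[0] - mid[0]
    xyz[:, 1] += xy[1] - mid[1]
    xyz[:, 2] += (z_ref + depth) - xyz[:, 2].min()
    return xyz


# ---------------------------------------------------------------------------
# Planted-truth helpers (deliberately separate from the analysis modules)
# ---------------------------------------------------------------------------

def _brute_min_and_contacts(xa, xb, box, cutoff=0.54):
    """Naive double loop: min distance and contact count between two heavy
    atom sets (minimum image in all three dimensions)."""
    dmin = np.inf
    n = 0
    for i in range(xa.shape[0]):
        d = min_image_displacement(xb - xa[i], np.asarray(box))
        r = np.sqrt((d * d).sum(axis=1))
        dmin = min(dmin, float(r.min()))
        n += int((r <= cutoff).sum())
    return dmin, n


def _smoothed_thickness_truth(head_xy_up, head_z_up, head_xy_lo, head_z_lo,
                              box, spacing, radius):
    """Reference thickness field: the radius-smoothed phosphate-to-phosphate
    separation evaluated on the noise-free planted configuration, minimum
    image in x-y — the exact expectation of the estimator under jitter."""
    lx, ly = box[0], box[1]
    nx = max(1, int(round(lx / spacing)))
    ny = max(1, int(round(ly / spacing)))
    sx, sy = lx / nx, ly / ny
    field = np.full((nx, ny), np.nan)
    for i in range(nx):
        for j in range(ny):
            cx, cy = (i + 0.5) * sx, (j + 0.5) * sy
            vals = []
            for xy, z in ((head_xy_up, head_z_up), (head_xy_lo, head_z_lo)):
                dx = xy[:, 0] - cx
                dy = xy[:, 1] - cy
                dx -= lx * np.round(dx / lx)
                dy -= ly * np.round(dy / ly)
                sel = dx ** 2 + dy ** 2 <= radius ** 2
                vals.append(z[sel].mean() if sel.any() else np.nan)
            field[i, j] = vals[0] - vals[1]
    return (0.0, 0.0), (sx, sy), field


# ---------------------------------------------------------------------------
# Main entry
# ---------------------------------------------------------------------------

def generate_system(params: GeneratorParams
                    ) -> tuple[System, Trajectory, GroundTruth]:
    """Generate a bilayer(+peptide) system, an i.i.d.-jitter trajectory and
    the planted ground truth.  Deterministic given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    box = np.asarray(params.box, dtype=float)
    nlip = params.n_lipids_per_leaflet

    sites = _lattice(nlip, box[0], box[1])

    names: list[str] = []
    resname: list[str] = []
    resseq: list[int] = []
    chain: list[str] = []
    kind: list[str] = []
    group: list[str] = []
    coords: list[np.ndarray] = []
    mol_index: list[int] = []
    mol = -1

    # ---- peptides -----------------------------------------------------
    depths = params.per_chain(params.peptide_depth)
    tilts = params.per_chain(params.peptide_tilt)
    peptides: list[PeptideStructure] = []
    pep_xyz: list[np.ndarray] = []

    # clean bilayer center (before the global offset): mean of leaflet means
    up_z_plane = params.leaflet_z - (
        params.dimple.depth_at(sites[:, 0], sites[:, 1])
        if params.dimple else np.zeros(nlip))
    clean_center = 0.5 * (float(np.mean(up_z_plane)) + -params.leaflet_z)

    cx, cy = box[0] / 2.0, box[1] / 2.0
    if params.n_peptides >= 1:
        for c_i in range(params.n_peptides):
            peptides.append(ideal_helix(params.peptide_length,
                                        helix_window=params.helix_window))
        if params.n_peptides == 1:
            pep_xyz.append(_place_peptide(peptides[0], tilts[0], depths[0],
                                          (cx, cy), clean_center))
        elif params.dimer_contact:
            # V-shaped pair: C-terminal (high-x) ends close, N-terminal ends
            # splayed in y so contacts are confined to the C-terminal region
            gap = 0.5
            v_deg = -10.0
            xa = _place_peptide(peptides[0], tilts[0], depths[0],
                                (cx, cy - gap / 2.0), clean_center)
            xb = _place_peptide(peptides[1], tilts[1], depths[1],
                                (cx, cy + gap / 2.0), clean_center,
                                v_angle=v_deg)
            # pivot the rotated chain back so its C-terminal end (max x)
            # returns to the intended y
            shift = xb[np.argmax(xb[:, 0]), 1] - (cy + gap / 2.0)
            xb[:, 1] -= shift
            pep_xyz += [xa, xb]
        else:
            sep = max(params.interchain_min_distance + 0.8, 1.0)
            pep_xyz.append(_place_peptide(peptides[0], tilts[0], depths[0],
                                          (cx, cy - sep / 2.0), clean_center))
            pep_xyz.append(_place_peptide(peptides[1], tilts[1], depths[1],
                                          (cx, cy + sep / 2.0), clean_center))

        for c_i, (pep, xyz) in enumerate(zip(peptides, pep_xyz)):
            mol += 1
            cid = chr(ord("A") + c_i)
            for a in range(xyz.shape[0]):
                names.append(pep.names[a])
                resname.append(pep.residue_names[a])
                resseq.append(pep.residue_numbers[a])
                chain.append(cid)
                kind.append(MoleculeKind.PEPTIDE.value)
                group.append(LipidGroup.NONE.value)
                coords.append(xyz[a])
                mol_index.append(mol)

    # ---- lipids -------------------------------------------------------
    head_xy = {Leaflet.UPPER: [], Leaflet.LOWER: []}
    head_z = {Leaflet.UPPER: [], Leaflet.LOWER: []}
    leaflet_labels: list[str] = []
    lipid_resseq = 0
    for leaflet, sign in ((Leaflet.UPPER, 1.0), (Leaflet.LOWER, -1.0)):
        for s in range(nlip):
            azimuth = rng.uniform(0.0, 2.0 * math.pi)
            local, lnames = _lipid_template(params, leaflet is Leaflet.UPPER,
                                            azimuth)
            if leaflet is Leaflet.UPPER:
                zhead = float(up_z_plane[s])
            else:
                zhead = -params.leaflet_z
            origin = np.array([sites[s, 0], sites[s, 1], zhead])
            xyz = local + origin
            mol += 1
            lipid_resseq += 1
            for a, nm in enumerate(lnames):
                names.append(nm)
                resname.append("POPG")
                resseq.append(lipid_resseq)
                chain.append("")
                kind.append(MoleculeKind.LIPID.value)
                group.append(LipidGroup.HEAD.value if nm == "P"
                             else LipidGroup.TAIL.value)
                coords.append(xyz[a])
                mol_index.append(mol)
            head_xy[leaflet].append(origin[:2])
            head_z[leaflet].append(zhead)
            leaflet_labels.append(leaflet.value)

    clean = np.array(coords)
    clean[:, 2] += params.center_offset

    charge, c6, c12, elements = _parameters_for(names, resname)
    system = System(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        residue_index=_global_residue_index(resseq, kind, chain),
        residue_name=np.array(resname, dtype=object),
        chain_id=np.array(chain, dtype=object),
        molecule_kind=np.array(kind, dtype=object),
        molecule_index=np.array(mol_index, dtype=int),
        charge=charge, c6=c6, c12=c12,
        lipid_group=np.array(group, dtype=object),
    )

    # ---- ground truth -------------------------------------------------
    up_xy = np.array(head_xy[Leaflet.UPPER])
    lo_xy = np.array(head_xy[Leaflet.LOWER])
    up_zz = np.array(head_z[Leaflet.UPPER])
    lo_zz = np.array(head_z[Leaflet.LOWER])
    origin, spacing, field = _smoothed_thickness_truth(
        up_xy, up_zz, lo_xy, lo_zz, box, spacing=0.25, radius=1.0)

    scd0 = 0.5 * (3.0 * math.cos(math.radians(params.tail_tilt_theta)) ** 2
                  - 1.0)
    if params.explicit_hydrogens:
        scd_carbons = [scd0] * params.tail_carbons
    else:  # terminal carbons are excluded from reconstruction profiles
        scd_carbons = [float("nan")] + [scd0] * (params.tail_carbons - 2) \
            + [float("nan")]

    helix_res: dict[str, list[int]] = {}
    minz: dict[str, list[float]] = {}
    heavy = system.heavy_mask
    for c_i, pep in enumerate(peptides):
        cid = chr(ord("A") + c_i)
        helix_res[cid] = pep.planted_helix_residues()
        atoms = system.chain_atoms(cid)
        zs = []
        for res in system.chain_residues(cid):
            zs.append(float(clean[res, 2].min())
                      - (clean_center + params.center_offset))
        minz[cid] = zs

    contacts = None
    dmin = None
    if params.n_peptides == 2:
        ia = system.chain_atoms("A")
        ib = system.chain_atoms("B")
        ia = ia[heavy[ia]]
        ib = ib[heavy[ib]]
        dmin, _ = _brute_min_and_contacts(clean[ia], clean[ib], box)
        if dmin < params.interchain_min_distance:
            raise ValueError(
                f"peptide placement violates interchain_min_distance: "
                f"min distance {dmin:.3f} nm < "
                f"{params.interchain_min_distance} nm")
        contacts = {}
        res1 = np.asarray([system.residue_index[i] for i in ia])
        for lab, lo, hi in (("1-19", 1, 19), ("20-37", 20, 37)):
            sa = _region_atoms(system, "A", lo, hi)
            sb = _region_atoms(system, "B", lo, hi)
            _, n = _brute_min_and_contacts(clean[sa], clean[sb], box)
            contacts[lab] = n

    truth = GroundTruth(
        leaflet_labels=leaflet_labels,
        thickness_grid_origin=origin,
        thickness_grid_spacing=spacing,
        thickness_smoothing_radius=1.0,
        thickness_field=field,
        scd_per_carbon=scd_carbons,
        scd_value=scd0,
        contact_counts=contacts,
        min_interchain_distance=dmin,
        helix_residues=helix_res,
        per_residue_min_z=minz,
        bilayer_center_offset=clean_center + params.center_offset,
        n_lipids=2 * nlip,
    )

    # ---- frames: i.i.d. rigid per-molecule jitter ---------------------
    n_mol = mol + 1
    mol_of_atom = np.asarray(mol_index)
    frames = []
    for k in range(params.n_frames):
        disp = rng.normal(0.0, params.jitter_sigma, size=(n_mol, 3)) \
            if params.jitter_sigma > 0 else np.zeros((n_mol, 3))
        xyz = clean + disp[mol_of_atom]
        frames.append(Frame(time=k * params.frame_dt, coordinates=xyz,
                            box=box.copy()))
    traj = Trajectory(frames=frames, topology=system)
    return system, traj, truth


def _region_atoms(system: System, cid: str, lo: int, hi: int) -> np.ndarray:
    """Heavy atoms of 1-based residue positions lo..hi of one chain."""
    residues = system.chain_residues(cid)
    idx = np.concatenate([residues[r - 1] for r in range(lo, hi + 1)
                          if r - 1 < len(residues)])
    return idx[system.heavy_mask[idx]]


def _global_residue_index(resseq, kind, chain) -> np.ndarray:
    """0-based global residue index from per-atom residue numbers: a new
    residue starts whenever (chain, kind, resseq) changes."""
    out = np.empty(len(resseq), dtype=int)
    r = -1
    prev = None
    for i, key in enumerate(zip(chain, kind, resseq)):
        if key != prev:
            r += 1
            prev = key
        out[i] = r
    return out


def _parameters_for(names, resnames):
    """Charges, LJ parameters and elements by (residue, atom) rule set."""
    n = len(names)
    charge = np.zeros(n)
    c6 = np.zeros(n)
    c12 = np.zeros(n)
    elements = np.empty(n, dtype=object)
    for i, (nm, rn) in enumerate(zip(names, resnames)):
        if rn == "POPG":
            if nm == "P":
                elements[i] = "P"
                charge[i] = -1.0
                c6[i], c12[i] = _LJ_P
            elif nm.startswith("C"):
                elements[i] = "C"
                c6[i], c12[i] = _LJ_C
            else:
                elements[i] = "H"
        else:  # peptide
            elements[i] = "N" if nm == "N" else ("O" if nm == "O" else "C")
            c6[i], c12[i] = _LJ_C
            if rn == "LYS" and nm == "N":
                charge[i] = 1.0  # N-terminal amine of residue 1
            if rn in ("LYS", "ARG") and nm == "CB":
                charge[i] = 1.0  # charged side-chain pseudo-atom
    return charge, c6, c12, elements


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def parameter_table(system: System):
    """Collapse a System to the (residue_name, atom_name) parameter table."""
    import pandas as pd

    seen = {}
    for i in range(system.n_atoms):
        key = (str(system.residue_name[i]), str(system.names[i]))
        if key not in seen:
            seen[key] = dict(
                residue_name=key[0], atom_name=key[1],
                element=str(system.elements[i]),
                charge=float(system.charge[i]),
                c6=float(system.c6[i]), c12=float(system.c12[i]),
                molecule_kind=str(system.molecule_kind[i]),
                lipid_group=str(system.lipid_group[i]))
    return pd.DataFrame(list(seen.values()))


def _mdtraj_topology(system: System):
    import mdtraj as md
    from mdtraj.core import element as elem

    top = md.Topology()
    lut = {"H": elem.hydrogen, "C": elem.carbon, "N": elem.nitrogen,
           "O": elem.oxygen, "P": elem.phosphorus, "S": elem.sulfur}
    chain_obj = None
    prev_key = None
    res_obj = None
    prev_res = None
    for i in range(system.n_atoms):
        ckey = (str(system.chain_id[i]), str(system.molecule_kind[i]))
        if ckey != prev_key:
            chain_obj = top.add_chain()
            prev_key = ckey
        rkey = system.residue_index[i]
        if rkey != prev_res:
            res_obj = top.add_residue(str(system.residue_name[i]), chain_obj,
                                      resSeq=_resseq_of(system, i))
            prev_res = rkey
        top.add_atom(str(system.names[i]),
                     lut.get(str(system.elements[i]), elem.carbon), res_obj)
    return top


def _resseq_of(system: System, atom: int) -> int:
    """Residue number written to files: peptide residues restart per chain,
    lipids/water/ions number consecutively."""
    r = system.residue_index[atom]
    if system.molecule_kind[atom] == MoleculeKind.PEPTIDE.value:
        cid = system.chain_id[atom]
        first = np.flatnonzero(
            (system.chain_id == cid)
            & (system.molecule_kind == MoleculeKind.PEPTIDE.value))[0]
        return int(r - system.residue_index[first] + 1)
    mask = system.molecule_kind == MoleculeKind.LIPID.value
    if mask[atom]:
        lip_res = np.unique(system.residue_index[mask])
        return int(np.searchsorted(lip_res, r) + 1)
    return int(r + 1)


def write_files(system: System, traj: Trajectory, truth: GroundTruth,
                outdir: str | os.PathLike) -> dict[str, str]:
    """Write conf.gro (first frame), traj.gro (all frames), params.dat and
    ground_truth.json under *outdir*.  GRO stores coordinates at 0.001 nm
    precision, so round trips are exact to that resolution only."""
    import mdtraj as md

    os.makedirs(outdir, exist_ok=True)
    top = _mdtraj_topology(system)
    xyz = np.array([f.coordinates for f in traj.frames], dtype=np.float32)
    t = md.Trajectory(xyz=xyz, topology=top)
    t.unitcell_lengths = np.array([f.box for f in traj.frames],
                                  dtype=np.float32)
    t.unitcell_angles = np.full((traj.n_frames, 3), 90.0, dtype=np.float32)
    t.time = np.array([f.time for f in traj.frames]) * 1000.0  # ns -> ps
    paths = {
        "conf": os.path.join(outdir, "conf.gro"),
        "traj": os.path.join(outdir, "traj.gro"),
        "params": os.path.join(outdir, "params.dat"),
        "truth": os.path.join(outdir, "ground_truth.json"),
    }
    t[0].save_gro(paths["conf"])
    t.save_gro(paths["traj"])
    write_parameter_table(parameter_table(system), paths["params"])
    truth.to_json(paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# Presets mirroring the reference study conditions
# ---------------------------------------------------------------------------

PRESET_NAMES = ("1mono", "dimer1", "2mono", "pure")


def preset(name: str, seed: int = 0, n_frames: int = 51,
           jitter_sigma: float = 0.05) -> GeneratorParams:
    """Named study conditions.

    ``1mono``: one peptide inserted N-terminal-end first into the upper
    leaflet (deepest residue at +1.5 nm, the charged N-terminus anchored
    below the phosphate plane).  ``dimer1``: two peptides in C-terminal
    contact, chain A traversing into the lower leaflet (deepest residue at
    −2.0 nm, its N-terminus anchored at the lower phosphate plane), with a
    Gaussian thinning dimple planted under the dimer.  ``2mono``: two
    monomeric peptides separated by ≥ 2.5 nm, both bound to the upper
    leaflet.  ``pure``: peptide-free bilayer.
    """
    common = dict(seed=seed, n_frames=n_frames, jitter_sigma=jitter_sigma)
    if name == "pure":
        return GeneratorParams(n_peptides=0, **common)
    if name == "1mono":
        return GeneratorParams(n_peptides=1, peptide_depth=1.5,
                               peptide_tilt=10.0, **common)
    if name == "dimer1":
        return GeneratorParams(
            n_peptides=2, dimer_contact=True,
            peptide_depth=(-2.0, 0.3), peptide_tilt=(25.0, 2.0),
            interchain_min_distance=0.25,
            dimple=Dimple(amplitude=0.8, width=1.2, center=(2.5, 3.5)),
            **common)
    if name == "2mono":
        return GeneratorParams(n_peptides=2, dimer_contact=False,
                               peptide_depth=1.5, peptide_tilt=10.0,
                               interchain_min_distance=2.5, **common)
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
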