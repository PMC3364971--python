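"""Hydrogen-bond based secondary-structure assignment (Kabsch-Sander model)
and helix-content statistics.

A backbone hydrogen bond from the C=O of residue i to the N-H of residue j
exists when the electrostatic energy

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)   [kcal mol⁻¹]

(distances in angstrom) is below −0.5 kcal mol⁻¹.  Amide hydrogens absent
from the input are rebuilt at 1 Å from N along the C(i−1)→O(i−1) carbonyl
direction, the construction the original DSSP program uses.  n→n+4 bonded
stretches yield α-helix (H), n→n+3 3₁₀ (G), n→n+5 π (I); bridges yield
strand (E), unassigned turns T, tight CA bends S, else coil C.  Bridge
detection is intra-chain; each chain is assigned independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .system import Frame, System, TimeWindow, Trajectory

__all__ = [
    "HBOND_ENERGY_CUTOFF",
    "HELIX_CODES",
    "SecondaryStructureProfile",
    "HelixContent",
    "ks_hbond_energy",
    "assign_secondary_structure",
    "helix_content",
]

HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
_KS_PREFACTOR = 0.084 * 332.0  # kcal/mol·Å
_CLASH = 0.5  # angstrom
#: codes counted as "helical structure" by default
HELIX_CODES = frozenset({"H", "G", "I"})


@dataclass
class SecondaryStructureProfile:
    """Per-frame, per-residue structure codes for all peptide chains."""

    times: np.ndarray
    chains: np.ndarray  # per residue column
    residue_numbers: np.ndarray  # 1-based within chain
    codes: np.ndarray  # (n_frames, n_residues) of single-char strings

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{c}{r}" for c, r in zip(self.chains, self.residue_numbers)]
        df = pd.DataFrame(self.codes, columns=cols)
        df.insert(0, "time_ns", self.times)
        return df


@dataclass
class HelixContent:
    mean: float  # percent
    sd: float  # percent, over frames
    codes: frozenset
    window: TimeWindow


def ks_hbond_energy(c: np.ndarray, o: np.ndarray, n: np.ndarray,
                    h: np.ndarray) -> float:
    """Kabsch-Sander hydrogen-bond energy (kcal mol⁻¹) for an acceptor
    carbonyl (C, O) and donor amide (N, H), coordinates in nm.

    Atom clashes (any of the four distances below 0.5 Å) are treated as
    no-bond and return 0.
    """
    # nm -> angstrom
    c, o, n, h = (np.asarray(x, dtype=float) * 10.0 for x in (c, o, n, h))
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < _CLASH:
        return 0.0
    return _KS_PREFACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _chain_backbone(frame: Frame, system: System, chain: str):
    """(n_res, 4, 3) backbone coordinates N, CA, C, O; rows with missing
    atoms are NaN (those residues are coded C with a warning)."""
    residues = system.chain_residues(chain)
    bb = np.full((len(residues), 4, 3), np.nan)
    order = {"N": 0, "CA": 1, "C": 2, "O": 3}
    for r, idx in enumerate(residues):
        for i in idx:
            pos = order.get(str(system.names[i]))
            if pos is not None:
                bb[r, pos] = frame.coordinates[i]
        if np.isnan(bb[r]).any():
            warnings.warn(
                f"chain {chain} residue {r + 1}: incomplete backbone, "
                "coded C", stacklevel=2)
    return bb


def _amide_hydrogens(bb: np.ndarray) -> np.ndarray:
    """Rebuilt amide H per residue (NaN for residue 1, which has no
    preceding carbonyl, and for incomplete residues)."""
    n_res = bb.shape[0]
    h = np.full((n_res, 3), np.nan)
    for r in range(1, n_res):
        c_prev, o_prev = bb[r - 1, 2], bb[r - 1, 3]
        n = bb[r, 0]
        if np.isnan(c_prev).any() or np.isnan(o_prev).any() \
                or np.isnan(n).any():
            continue
        d = c_prev - o_prev
        nd = np.linalg.norm(d)
        if nd < 1e-9:
            continue
        h[r] = n + 0.1 * d / nd  # 1 angstrom in nm
    return h


def _hbond_matrix(bb: np.ndarray) -> np.ndarray:
    """bond[i, j]: C=O of residue i accepts from N-H of residue j."""
    n_res = bb.shape[0]
    h = _amide_hydrogens(bb)
    bond = np.zeros((n_res, n_res), dtype=bool)
    for i in range(n_res):
        if np.isnan(bb[i, 2]).any() or np.isnan(bb[i, 3]).any():
            continue
        for j in range(n_res):
            if abs(i - j) < 2:  # no bonds to self or sequence neighbours
                continue
            if np.isnan(h[j]).any() or np.isnan(bb[j, 0]).any():
                continue
            e = ks_hbond_energy(bb[i, 2], bb[i, 3], bb[j, 0], h[j])
            bond[i, j] = e < HBOND_ENERGY_CUTOFF
    return bond


def _assign_chain(bb: np.ndarray) -> np.ndarray:
    """DSSP-style codes for one chain from its backbone coordinates."""
    n = bb.shape[0]
    codes = np.full(n, "C", dtype="<U1")
    bond = _hbond_matrix(bb)

    def turn(i, k):
        return i + k < n and bond[i, i + k]

    # helices: two consecutive n-turns mark the bracketed stretch
    marks = {4: np.zeros(n, bool), 3: np.zeros(n, bool), 5: np.zeros(n, bool)}
    for k in (4, 3, 5):
        for i in range(1, n):
            if turn(i, k) and turn(i - 1, k):
                marks[k][i:i + k] = True

    # strand bridges (intra-chain, |i-j| >= 3)
    bridge = np.zeros(n, bool)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (bond[i - 1, j] and bond[j, i + 1]) or \
                   (bond[j - 1, i] and bond[i, j + 1])
            anti = (bond[i, j] and bond[j, i]) or \
                   (bond[i - 1, j + 1] and bond[j - 1, i + 1])
            if para or anti:
                bridge[i] = bridge[j] = True

    codes[marks[4]] = "H"
    codes[bridge & (codes == "C")] = "E"
    free = codes == "C"
    codes[marks[3] & free] = "G"
    free = codes == "C"
    codes[marks[5] & free] = "I"
    # turns: interior of any single n-turn
    isturn = np.zeros(n, bool)
    for k in (3, 4, 5):
        for i in range(n):
            if turn(i, k):
                isturn[i + 1:i + k] = True
    codes[isturn & (codes == "C")] = "T"
    # bends: CA direction change > 70 degrees
    for i in range(2, n - 2):
        if np.isnan(bb[i - 2:i + 3, 1]).any():
            continue
        u = bb[i, 1] - bb[i - 2, 1]
        v = bb[i + 2, 1] - bb[i, 1]
        cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        if cos < np.cos(np.radians(70.0)) and codes[i] == "C":
            codes[i] = "S"
    # incomplete backbones stay coil
    incomplete = np.isnan(bb.reshape(n, -1)).any(axis=1)
    codes[incomplete] = "C"
    return codes


def assign_secondary_structure(frame: Frame, system: System
                               ) -> dict[str, np.ndarray]:
    """Per-residue structure codes {H,G,I,E,T,S,C} for every peptide chain."""
    out = {}
    for chain in system.peptide_chain_ids():
        bb = _chain_backbone(frame, system, chain)
        out[chain] = _assign_chain(bb)
    if not out:
        raise ValueError("no peptide chains in system")
    return out


def secondary_structure_profile(traj: Trajectory,
                                window: TimeWindow | None = None
                                ) -> SecondaryStructureProfile:
    """Codes for every window frame and peptide residue."""
    if window is None:
        window = TimeWindow(traj.frames[0].time - 1e-9,
                            traj.frames[-1].time + 1e-9)
    idx = window.select(traj)
    system = traj.topology
    chains = system.peptide_chain_ids()
    cols_chain = []
    cols_res = []
    for c in chains:
        nres = len(system.chain_residues(c))
        cols_chain += [c] * nres
        cols_res += list(range(1, nres + 1))
    rows = []
    for i in idx:
        codes = assign_secondary_structure(traj.frames[i], system)
        rows.append(np.concatenate([codes[c] for c in chains]))
    return SecondaryStructureProfile(
        times=np.array([traj.frames[i].time for i in idx]),
        chains=np.array(cols_chain, dtype=object),
        residue_numbers=np.array(cols_res, dtype=int),
        codes=np.array(rows))


def helix_content(traj: Trajectory, window: TimeWindow | None = None,
                  codes: frozenset | set = HELIX_CODES,
                  per: str = "system") -> HelixContent | dict[str, HelixContent]:
    """Percentage of peptide residues in helical codes, mean ± sd over the
    window frames.  ``per='chain'`` returns one statistic per chain."""
    profile = secondary_structure_profile(traj, window)
    window = TimeWindow(profile.times[0] - 1e-9, profile.times[-1] + 1e-9)
    codes = frozenset(codes)
    helical = np.isin(profile.codes, sorted(codes))

    def stat(mask_cols):
        frac = 100.0 * helical[:, mask_cols].mean(axis=1)
        return HelixContent(mean=float(frac.mean()),
                            sd=float(frac.std(ddof=0)),
                            codes=codes, window=window)

    if per == "system":
        return stat(np.ones(profile.codes.shape[1], dtype=bool))
    if per == "chain":
        return {c: stat(profile.chains == c)
                for c in np.unique(profile.chains)}
    raise ValueError("per must be 'system' or 'chain'")
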