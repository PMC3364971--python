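"""Acyl-chain deuterium order parameters S_CD with a peptide-proximity
lipid filter.

S_CD = 0.5 <3 cos²θ − 1>, θ the angle between each C-H bond vector and the
membrane normal (+z), averaged over both hydrogens, the selected lipids and
the frames of the averaging window.  The range is [−0.5, 1]: −0.5 for bonds
perpendicular to the normal, 1 for parallel, 0 for isotropic orientations.

Hydrogens are used directly where the topology carries them; for united-atom
chains the two C-H unit vectors of each interior carbon are rebuilt with the
standard tetrahedral construction (perpendicular to the C(i−1)→C(i+1)
direction, symmetric about the local bisector plane); chain-terminal carbons
are then excluded from the profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .system import (
    Frame,
    MoleculeKind,
    System,
    TimeWindow,
    Trajectory,
    min_image_distance,
)

__all__ = [
    "OrderParameterProfile",
    "scd_kernel",
    "select_proximal_lipids",
    "scd_profile",
]

_COS_HALF_TETRA = 1.0 / math.sqrt(3.0)  # cos of half the H-C-H angle
_SIN_HALF_TETRA = math.sqrt(2.0 / 3.0)
_MAX_CH_BOND = 0.15  # nm, hydrogen-to-carbon association cutoff


@dataclass
class OrderParameterProfile:
    """Per-carbon S_CD along the acyl chain (1 = carbon bonded to the head
    group end).  ``n_samples`` counts C-H vectors accumulated per carbon;
    carbons with no samples (e.g. terminal carbons in united-atom mode)
    carry NaN."""

    carbon_index: np.ndarray  # 1-based position along the chain
    scd: np.ndarray
    n_samples: np.ndarray
    locality_cutoff: float | None
    window: TimeWindow

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"carbon_index": self.carbon_index,
                             "scd": self.scd,
                             "n_samples": self.n_samples})


def scd_kernel(cos_theta: np.ndarray) -> np.ndarray:
    """Order-parameter kernel 0.5 (3 cos²θ − 1) applied elementwise."""
    c = np.asarray(cos_theta, dtype=float)
    return 0.5 * (3.0 * c * c - 1.0)


def select_proximal_lipids(frame: Frame, system: System,
                           cutoff: float) -> np.ndarray:
    """Indices (into the lipid-molecule list) of lipids with any atom within
    *cutoff* (minimum image) of any non-hydrogen peptide atom.

    Without a peptide the filter is vacuous and all lipids are returned.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lipids = system.lipid_molecules()
    pep = np.flatnonzero(
        (system.molecule_kind == MoleculeKind.PEPTIDE.value)
        & system.heavy_mask)
    if pep.size == 0:
        return np.arange(len(lipids))
    pep_xyz = frame.coordinates[pep]
    out = []
    for li, atoms in enumerate(lipids):
        d = min_image_distance(frame.coordinates[atoms], pep_xyz, frame.box)
        if d.min() <= cutoff:
            out.append(li)
    return np.asarray(out, dtype=int)


def _tail_carbons(system: System) -> list[np.ndarray]:
    """Ordered tail-carbon atom indices per lipid (atom-order = chain
    position)."""
    out = []
    for atoms in system.lipid_molecules():
        mask = (system.lipid_group[atoms] == "tail") \
            & (system.elements[atoms] == "C")
        out.append(atoms[mask])
    return out


def _hydrogen_map(system: System, frame: Frame,
                  carbons: list[np.ndarray]) -> dict[int, np.ndarray]:
    """Tail hydrogens per carbon, assigned once by proximity (< 0.15 nm) in
    the given frame; bonding is assumed stable over the trajectory."""
    hmap: dict[int, list[int]] = {}
    for atoms_c, lipid in zip(carbons, system.lipid_molecules()):
        hyd = lipid[(system.elements[lipid] == "H")
                    & (system.lipid_group[lipid] == "tail")]
        if hyd.size == 0 or atoms_c.size == 0:
            continue
        d = min_image_distance(frame.coordinates[hyd],
                               frame.coordinates[atoms_c], frame.box)
        nearest = np.argmin(d, axis=1)
        for h, ci in zip(hyd, nearest):
            if d[np.flatnonzero(hyd == h)[0], ci] <= _MAX_CH_BOND:
                hmap.setdefault(int(atoms_c[ci]), []).append(int(h))
    return {c: np.asarray(h) for c, h in hmap.items()}


def _reconstructed_ch(xyz: np.ndarray) -> np.ndarray:
    """Two C-H unit vectors per interior carbon of one chain (n_c, 3) ->
    (n_c - 2, 2, 3), tetrahedral construction."""
    prev = xyz[:-2]
    cur = xyz[1:-1]
    nxt = xyz[2:]
    r1 = prev - cur
    r1 /= np.linalg.norm(r1, axis=1, keepdims=True)
    r2 = nxt - cur
    r2 /= np.linalg.norm(r2, axis=1, keepdims=True)
    b = r1 + r2
    b /= np.linalg.norm(b, axis=1, keepdims=True)
    n = np.cross(r1, r2)
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    u1 = -b * _COS_HALF_TETRA + n * _SIN_HALF_TETRA
    u2 = -b * _COS_HALF_TETRA - n * _SIN_HALF_TETRA
    return np.stack([u1, u2], axis=1)


def scd_profile(traj: Trajectory, cutoff: float | None = 1.0,
                window: TimeWindow | None = None) -> OrderParameterProfile:
    """Per-carbon S_CD averaged over both C-H bonds, the peptide-proximal
    lipids (all lipids if *cutoff* is None or no peptide is present) and the
    window frames."""
    system = traj.topology
    if window is None:
        window = TimeWindow(traj.frames[0].time - 1e-9,
                            traj.frames[-1].time + 1e-9)
    carbons = _tail_carbons(system)
    n_pos = max((c.size for c in carbons), default=0)
    if n_pos == 0:
        raise ValueError("no tail carbons in topology")

    frames = window.select(traj)
    hmap = _hydrogen_map(system, traj.frames[frames[0]], carbons)
    explicit = len(hmap) > 0

    acc = np.zeros(n_pos)
    n_samp = np.zeros(n_pos, dtype=int)
    any_selected = False
    for fi in frames:
        frame = traj.frames[fi]
        if cutoff is None:
            selected = np.arange(len(carbons))
        else:
            selected = select_proximal_lipids(frame, system, cutoff)
        if selected.size == 0:
            continue
        any_selected = True
        for li in selected:
            cx = carbons[li]
            xyz = frame.coordinates[cx]
            if explicit:
                for pos, c_atom in enumerate(cx):
                    hyd = hmap.get(int(c_atom))
                    if hyd is None:
                        continue
                    vec = frame.coordinates[hyd] - frame.coordinates[c_atom]
                    cos = vec[:, 2] / np.linalg.norm(vec, axis=1)
                    acc[pos] += scd_kernel(cos).sum()
                    n_samp[pos] += cos.size
            else:
                if cx.size < 3:
                    continue
                ch = _reconstructed_ch(xyz)  # (n-2, 2, 3), unit vectors
                cos = ch[:, :, 2]
                acc[1:cx.size - 1] += scd_kernel(cos).sum(axis=1)
                n_samp[1:cx.size - 1] += 2
    if not any_selected:
        raise ValueError("no lipids selected in any window frame")
    with np.errstate(invalid="ignore"):
        scd = np.where(n_samp > 0, acc / np.maximum(n_samp, 1), np.nan)
    return OrderParameterProfile(
        carbon_index=np.arange(1, n_pos + 1), scd=scd, n_samples=n_samp,
        locality_cutoff=cutoff, window=window)
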