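"""Atomic contacts between peptide regions and the monomer/dimer
association criterion.

An atomic contact is a pair of non-hydrogen atoms within 0.54 nm (inclusive;
minimum image in all three box dimensions, since chains may straddle the
periodic wall).  Two chains are in the monomeric state when their minimum
non-hydrogen inter-chain distance exceeds 1.4 nm in every frame of the
assessment window; otherwise they are associated.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .system import Frame, System, TimeWindow, Trajectory, min_image_distance

__all__ = [
    "CONTACT_CUTOFF",
    "ASSOCIATION_THRESHOLD",
    "DEFAULT_REGIONS",
    "AssociationState",
    "ContactSeries",
    "AssociationResult",
    "count_atomic_contacts",
    "interchain_contact_series",
    "association_state",
]

CONTACT_CUTOFF = 0.54  # nm
ASSOCIATION_THRESHOLD = 1.4  # nm
#: N-terminal membrane-binding region vs C-terminal amyloidogenic region.
DEFAULT_REGIONS = ((1, 19), (20, 37))


class AssociationState(str, Enum):
    MONOMERIC = "monomeric"
    ASSOCIATED = "associated"


@dataclass
class ContactSeries:
    """Per-frame inter-chain contact counts for one region pair."""

    label: str
    times: np.ndarray
    counts: np.ndarray
    cutoff: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times,
                             f"n_contacts_{self.label}": self.counts})


@dataclass
class AssociationResult:
    state: AssociationState
    times: np.ndarray
    min_distance: np.ndarray  # per frame, nm
    threshold: float


def count_atomic_contacts(frame: Frame, sel_a: np.ndarray, sel_b: np.ndarray,
                          cutoff: float = CONTACT_CUTOFF,
                          system: System | None = None) -> int:
    """Number of atom pairs (a in sel_a, b in sel_b) within *cutoff*,
    inclusive, minimum image.  Selections must be disjoint; hydrogens are
    dropped when *system* is given (contacts are defined over non-hydrogen
    atoms)."""
    sel_a = np.asarray(sel_a, dtype=int)
    sel_b = np.asarray(sel_b, dtype=int)
    if np.intersect1d(sel_a, sel_b).size:
        raise ValueError("contact selections overlap")
    if system is not None:
        sel_a = sel_a[system.heavy_mask[sel_a]]
        sel_b = sel_b[system.heavy_mask[sel_b]]
    if sel_a.size == 0 or sel_b.size == 0:
        return 0
    d = min_image_distance(frame.coordinates[sel_a],
                           frame.coordinates[sel_b], frame.box)
    return int((d <= cutoff).sum())


def _region_atoms(system: System, chain: str,
                  region: tuple[int, int]) -> np.ndarray:
    """Non-hydrogen atoms of 1-based residue positions lo..hi of a chain."""
    lo, hi = region
    residues = system.chain_residues(chain)
    if not (1 <= lo <= hi <= len(residues)):
        raise ValueError(f"region {region} outside chain {chain!r} "
                         f"({len(residues)} residues)")
    idx = np.concatenate(residues[lo - 1:hi])
    return idx[system.heavy_mask[idx]]


def _two_chains(system: System) -> tuple[str, str]:
    chains = system.peptide_chain_ids()
    if len(chains) < 2:
        raise ValueError("need two peptide chains")
    return chains[0], chains[1]


def interchain_contact_series(traj: Trajectory,
                              region_a: tuple[int, int],
                              region_b: tuple[int, int] | None = None,
                              cutoff: float = CONTACT_CUTOFF) -> ContactSeries:
    """Per-frame contacts between residue region_a of one chain and
    region_b of the other (region_b defaults to region_a).

    For asymmetric region pairs both orderings are counted, so the series is
    invariant under relabelling the two chains.
    """
    system = traj.topology
    ca, cb = _two_chains(system)
    if region_b is None:
        region_b = region_a
    a1 = _region_atoms(system, ca, region_a)
    b2 = _region_atoms(system, cb, region_b)
    pairs = [(a1, b2)]
    if tuple(region_a) != tuple(region_b):
        pairs.append((_region_atoms(system, ca, region_b),
                      _region_atoms(system, cb, region_a)))
    counts = []
    for frame in traj.frames:
        n = sum(count_atomic_contacts(frame, pa, pb, cutoff)
                for pa, pb in pairs)
        counts.append(n)
    label = f"{region_a[0]}-{region_a[1]}/{region_b[0]}-{region_b[1]}"
    return ContactSeries(label=label, times=traj.times,
                         counts=np.asarray(counts, dtype=int), cutoff=cutoff)


def min_interchain_distance(frame: Frame, system: System) -> float:
    """Minimum non-hydrogen inter-chain distance (minimum image)."""
    ca, cb = _two_chains(system)
    ia = system.chain_atoms(ca)
    ib = system.chain_atoms(cb)
    ia = ia[system.heavy_mask[ia]]
    ib = ib[system.heavy_mask[ib]]
    d = min_image_distance(frame.coordinates[ia], frame.coordinates[ib],
                           frame.box)
    return float(d.min())


def association_state(traj: Trajectory,
                      threshold: float = ASSOCIATION_THRESHOLD,
                      window: TimeWindow | None = None) -> AssociationResult:
    """Monomeric iff the minimum inter-chain distance exceeds *threshold*
    in every window frame."""
    if window is None:
        window = TimeWindow(traj.frames[0].time - 1e-9,
                            traj.frames[-1].time + 1e-9)
    idx = window.select(traj)
    dmin = np.array([min_interchain_distance(traj.frames[i], traj.topology)
                     for i in idx])
    times = np.array([traj.frames[i].time for i in idx])
    state = (AssociationState.MONOMERIC if bool(np.all(dmin > threshold))
             else AssociationState.ASSOCIATED)
    return AssociationResult(state=state, times=times, min_distance=dmin,
                             threshold=threshold)
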