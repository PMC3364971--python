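"""Shared fixtures: small synthetic systems generated in memory.

Session-scoped generator outputs are reused across test modules; every
fixture is deterministic (fixed seeds).
"""

from __future__ import annotations

import numpy as np
import pytest

from memperturb.generate import GeneratorParams, generate_system, preset
from memperturb.system import Frame, System, Trajectory


@pytest.fixture(scope="session")
def pure_clean():
    """Peptide-free bilayer, zero jitter, 2 frames."""
    return generate_system(preset("pure", seed=11, n_frames=2,
                                  jitter_sigma=0.0))


@pytest.fixture(scope="session")
def mono_clean():
    """One peptide, zero jitter, 2 frames."""
    return generate_system(preset("1mono", seed=12, n_frames=2,
                                  jitter_sigma=0.0))


@pytest.fixture(scope="session")
def dimer_clean():
    """Contact dimer with dimple, zero jitter, 2 frames."""
    return generate_system(preset("dimer1", seed=13, n_frames=2,
                                  jitter_sigma=0.0))


@pytest.fixture(scope="session")
def mono_noisy():
    """One peptide, jitter 0.05 nm, 50 frames (planted-recovery checks)."""
    return generate_system(preset("1mono", seed=14, n_frames=50,
                                  jitter_sigma=0.05))


@pytest.fixture(scope="session")
def pure_noisy():
    """Peptide-free bilayer, jitter 0.05 nm, 50 frames."""
    return generate_system(preset("pure", seed=15, n_frames=50,
                                  jitter_sigma=0.05))


def tiny_system(coords, *, charges=None, elements=None, kinds=None,
                groups=None, resnames=None, residue_index=None,
                chain_id=None, c6=None, c12=None, box=(5.0, 7.0, 9.0),
                time=0.0):
    """Hand-built System + Frame for focused unit tests."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]

    def arr(v, default, dtype=object):
        if v is None:
            v = [default] * n
        return np.asarray(v, dtype=dtype)

    system = System(
        names=arr(None, "X"),
        elements=arr(elements, "C"),
        residue_index=arr(residue_index, 0, int) if residue_index is not None
        else np.zeros(n, dtype=int),
        residue_name=arr(resnames, "UNK"),
        chain_id=arr(chain_id, ""),
        molecule_kind=arr(kinds, "ion"),
        molecule_index=np.arange(n),
        charge=arr(charges, 0.0, float),
        c6=arr(c6, 0.0, float),
        c12=arr(c12, 0.0, float),
        lipid_group=arr(groups, "none"),
    )
    frame = Frame(time=time, coordinates=coords,
                  box=np.asarray(box, dtype=float))
    return system, frame


def flat_bilayer_system(n_per_leaflet=8, leaflet_z=2.2,
                        box=(5.0, 7.0, 9.0), upper_z=None, lower_z=None):
    """Minimal bilayer of bare phosphorus head atoms (one per lipid)."""
    rng = np.random.default_rng(0)
    n = n_per_leaflet
    xy = np.column_stack([rng.uniform(0, box[0], 2 * n),
                          rng.uniform(0, box[1], 2 * n)])
    z = np.concatenate([
        np.full(n, leaflet_z) if upper_z is None else np.asarray(upper_z),
        np.full(n, -leaflet_z) if lower_z is None else np.asarray(lower_z),
    ])
    coords = np.column_stack([xy, z])
    system, frame = tiny_system(
        coords,
        elements=["P"] * 2 * n,
        kinds=["lipid"] * 2 * n,
        groups=["head"] * 2 * n,
        resnames=["POPG"] * 2 * n,
        box=box,
    )
    system.residue_index = np.arange(2 * n)
    return system, frame


def as_trajectory(system, frames):
    return Trajectory(frames=list(frames), topology=system)
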