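"""Insertion-depth profiles, leaflet-resolved phosphorus z-displacement and
gridded bilayer-thickness maps.

All quantities use the centered convention: the bilayer midplane is z = 0,
the upper leaflet z > 0 and the lower z < 0.  The per-residue position is the
z of the residue's lowest atom; the peptide insertion depth is the z of the
most deeply inserted residue, time averaged over a window.  Thickness is the
local (radius-smoothed) phosphate-to-phosphate separation on a rectangular
grid covering the membrane plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .system import (
    Frame,
    Leaflet,
    System,
    TimeWindow,
    Trajectory,
    assign_leaflets,
    center_on_bilayer,
)

__all__ = [
    "ResidueZProfile",
    "ThicknessMap",
    "residue_z_profile",
    "insertion_depth",
    "phosphorus_z_displacement",
    "thickness_map",
]


@dataclass
class ResidueZProfile:
    """Per-residue z (nm, centered frame) of one peptide chain at one time:
    the minimum over the residue's atoms."""

    chain: str
    residue_numbers: np.ndarray  # 1-based
    residue_names: np.ndarray
    z: np.ndarray
    time: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "residue": self.residue_numbers,
            "residue_name": self.residue_names,
            "z_nm": self.z,
        })


@dataclass
class ThicknessMap:
    """Time-averaged local bilayer thickness on a rectangular x-y grid.

    ``values[i, j]`` is the thickness (nm) at cell center
    ``origin + ((i + 0.5) sx, (j + 0.5) sy)``; NaN marks cells where one
    leaflet had no phosphorus atom within the smoothing radius in any frame.
    ``counts`` holds the total number of phosphorus samples (both leaflets,
    all frames) per cell.
    """

    origin: tuple[float, float]
    spacing: tuple[float, float]
    values: np.ndarray
    counts: np.ndarray
    window: TimeWindow
    smoothing_radius: float

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values)


def residue_z_profile(frame: Frame, system: System, chain: str,
                      centered: bool = False) -> ResidueZProfile:
    """z of the lowest atom of every residue of *chain*, centered frame."""
    if not centered:
        frame = center_on_bilayer(frame, system)
    residues = system.chain_residues(chain)  # raises on unknown chain
    z = np.array([frame.coordinates[idx, 2].min() for idx in residues])
    nums = np.arange(1, len(residues) + 1)
    rnames = np.array([str(system.residue_name[idx[0]]) for idx in residues],
                      dtype=object)
    return ResidueZProfile(chain=chain, residue_numbers=nums,
                           residue_names=rnames, z=z, time=frame.time)


def insertion_depth(traj: Trajectory, chain: str,
                    window: TimeWindow) -> float:
    """Time-averaged z of the most deeply inserted residue of *chain*.

    Positive means the deepest point lies in the upper leaflet, negative in
    the lower leaflet.
    """
    idx = window.select(traj)
    vals = [residue_z_profile(traj.frames[i], traj.topology, chain).z.min()
            for i in idx]
    return float(np.mean(vals))


def phosphorus_z_displacement(traj: Trajectory, leaflet: Leaflet | str,
                              window: TimeWindow) -> float:
    """Head-group disorder: per frame, the RMS deviation of the leaflet's
    phosphorus z-coordinates about their mean, time averaged over window."""
    leaflet = Leaflet(leaflet)
    system = traj.topology
    p_idx = system.lipid_phosphorus_indices()
    out = []
    for i in window.select(traj):
        frame = traj.frames[i]
        assignment = assign_leaflets(frame, system)
        lipids = assignment.of(leaflet)
        if lipids.size == 0:
            raise ValueError(f"{leaflet.value} leaflet is empty in frame {i}")
        z = frame.coordinates[p_idx[lipids], 2]
        out.append(np.sqrt(np.mean((z - z.mean()) ** 2)))
    return float(np.mean(out))


def thickness_map(traj: Trajectory, grid_spacing: float = 0.25,
                  smoothing_radius: float = 1.0,
                  window: TimeWindow | None = None) -> ThicknessMap:
    """Local phosphate-to-phosphate bilayer thickness over the x-y plane.

    Per frame and grid cell, the thickness is the mean z of upper-leaflet
    phosphorus atoms within *smoothing_radius* of the cell center (minimum
    image in x-y) minus the same for the lower leaflet; cell values are
    averaged over the frames where both leaflets contributed samples.
    """
    if grid_spacing <= 0 or smoothing_radius <= 0:
        raise ValueError("grid_spacing and smoothing_radius must be > 0")
    if window is None:
        window = TimeWindow(traj.frames[0].time - 1e-9,
                            traj.frames[-1].time + 1e-9)
    system = traj.topology
    p_idx = system.lipid_phosphorus_indices()
    frames = window.select(traj)

    box = traj.frames[frames[0]].box
    lx, ly = float(box[0]), float(box[1])
    nx = max(1, int(round(lx / grid_spacing)))
    ny = max(1, int(round(ly / grid_spacing)))
    sx, sy = lx / nx, ly / ny
    cxs = (np.arange(nx) + 0.5) * sx
    cys = (np.arange(ny) + 0.5) * sy

    total = np.zeros((nx, ny))
    nframes_def = np.zeros((nx, ny), dtype=int)
    counts = np.zeros((nx, ny), dtype=int)
    r2 = smoothing_radius ** 2

    for i in frames:
        frame = traj.frames[i]
        assignment = assign_leaflets(frame, system)
        means = {}
        ns = {}
        for leaflet in (Leaflet.UPPER, Leaflet.LOWER):
            lipids = assignment.of(leaflet)
            if lipids.size == 0:
                raise ValueError(
                    f"{leaflet.value} leaflet empty in frame {i}")
            xyz = frame.coordinates[p_idx[lipids]]
            dx = xyz[:, 0][None, :] - cxs[:, None]
            dy = xyz[:, 1][None, :] - cys[:, None]
            dx -= lx * np.round(dx / lx)
            dy -= ly * np.round(dy / ly)
            # membership per (cell_x, cell_y, atom)
            d2 = dx[:, None, :] ** 2 + dy[None, :, :] ** 2
            mask = d2 <= r2
            n = mask.sum(axis=2)
            zsum = (mask * xyz[:, 2][None, None, :]).sum(axis=2)
            with np.errstate(invalid="ignore"):
                means[leaflet] = np.where(n > 0, zsum / np.maximum(n, 1),
                                          np.nan)
            ns[leaflet] = n
        both = (ns[Leaflet.UPPER] > 0) & (ns[Leaflet.LOWER] > 0)
        thick = means[Leaflet.UPPER] - means[Leaflet.LOWER]
        total[both] += thick[both]
        nframes_def += both
        counts += ns[Leaflet.UPPER] + ns[Leaflet.LOWER]

    with np.errstate(invalid="ignore"):
        values = np.where(nframes_def > 0, total / np.maximum(nframes_def, 1),
                          np.nan)
    return ThicknessMap(origin=(0.0, 0.0), spacing=(sx, sy), values=values,
                        counts=counts, window=window,
                        smoothing_radius=smoothing_radius)
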