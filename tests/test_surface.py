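"""Depth profiles, z-displacement and thickness maps, checked against
planted truth and naive reference implementations."""

import numpy as np
import pytest

from memperturb.generate import generate_system, preset, Dimple
from memperturb.surface import (
    insertion_depth,
    phosphorus_z_displacement,
    residue_z_profile,
    thickness_map,
)
from memperturb.system import Frame, Leaflet, TimeWindow, Trajectory, \
    assign_leaflets

from conftest import flat_bilayer_system, as_trajectory

ALL = TimeWindow(-1.0, 1e9)


def naive_thickness(traj, spacing, radius, window):
    """Reference: plain loops, no vectorization."""
    system = traj.topology
    p_idx = system.lipid_phosphorus_indices()
    frames = window.select(traj)
    box = traj.frames[frames[0]].box
    nx = int(round(box[0] / spacing))
    ny = int(round(box[1] / spacing))
    sx, sy = box[0] / nx, box[1] / ny
    out = np.full((nx, ny), np.nan)
    cnt = np.zeros((nx, ny))
    for i in range(nx):
        for j in range(ny):
            cx, cy = (i + 0.5) * sx, (j + 0.5) * sy
            vals = []
            for fi in frames:
                fr = traj.frames[fi]
                lab = assign_leaflets(fr, system)
                zs = {}
                for leaf in (Leaflet.UPPER, Leaflet.LOWER):
                    acc = []
                    for li in lab.of(leaf):
                        x, y, z = fr.coordinates[p_idx[li]]
                        dx = x - cx - box[0] * round((x - cx) / box[0])
                        dy = y - cy - box[1] * round((y - cy) / box[1])
                        if dx * dx + dy * dy <= radius * radius:
                            acc.append(z)
                    zs[leaf] = acc
                if zs[Leaflet.UPPER] and zs[Leaflet.LOWER]:
                    vals.append(np.mean(zs[Leaflet.UPPER])
                                - np.mean(zs[Leaflet.LOWER]))
            if vals:
                out[i, j] = np.mean(vals)
    return out


class TestResidueZ:
    def test_planted_min_z_recovered_exactly(self, mono_clean):
        system, traj, truth = mono_clean
        prof = residue_z_profile(traj.frames[0], system, "A")
        assert np.abs(prof.z - truth.per_residue_min_z["A"]).max() < 1e-9

    def test_unknown_chain_errors(self, mono_clean):
        system, traj, _ = mono_clean
        with pytest.raises(KeyError):
            residue_z_profile(traj.frames[0], system, "Z")


class TestInsertionDepth:
    def test_planted_depth_exact(self, mono_clean):
        system, traj, truth = mono_clean
        d = insertion_depth(traj, "A", ALL)
        assert d == pytest.approx(min(truth.per_residue_min_z["A"]),
                                  abs=1e-9)
        assert d == pytest.approx(1.5, abs=1e-9)  # the preset condition

    def test_stationary_windows_agree(self, mono_clean):
        _, traj, _ = mono_clean
        t0, t1 = traj.frames[0].time, traj.frames[-1].time
        a = insertion_depth(traj, "A", TimeWindow(t0 - 0.1, t0 + 0.1))
        b = insertion_depth(traj, "A", TimeWindow(t1 - 0.1, t1 + 0.1))
        assert a == pytest.approx(b, abs=1e-12)

    def test_rigid_shift_moves_depth_exactly(self, mono_clean):
        """Translating the peptide down by δ lowers the depth by δ."""
        system, traj, _ = mono_clean
        delta = 0.4
        base = insertion_depth(traj, "A", ALL)
        pep = system.chain_atoms("A")
        frames = []
        for fr in traj.frames:
            c = fr.coordinates.copy()
            c[pep, 2] -= delta
            frames.append(Frame(time=fr.time, coordinates=c, box=fr.box))
        shifted = Trajectory(frames=frames, topology=system)
        assert insertion_depth(shifted, "A", ALL) == pytest.approx(
            base - delta, abs=1e-9)

    def test_empty_window_errors(self, mono_clean):
        _, traj, _ = mono_clean
        with pytest.raises(ValueError):
            insertion_depth(traj, "A", TimeWindow(900.0, 901.0))


class TestZDisplacement:
    def test_coplanar_leaflet_is_zero(self, pure_clean):
        _, traj, _ = pure_clean
        assert phosphorus_z_displacement(traj, "upper", ALL) == pytest.approx(
            0.0, abs=1e-12)

    def test_two_point_rms(self):
        system, frame = flat_bilayer_system(
            n_per_leaflet=2, upper_z=np.array([2.2 + 0.3, 2.2 - 0.3]),
            lower_z=np.array([-2.2, -2.2]))
        traj = as_trajectory(system, [frame])
        assert phosphorus_z_displacement(traj, "upper", ALL) == \
            pytest.approx(0.3, abs=1e-12)

    def test_whole_leaflet_translation_invariance(self, pure_clean):
        system, traj, _ = pure_clean
        base = phosphorus_z_displacement(traj, "upper", ALL)
        frames = []
        p = system.lipid_phosphorus_indices()
        upper = p[traj.frames[0].coordinates[p, 2] > 0]
        for fr in traj.frames:
            c = fr.coordinates.copy()
            c[upper, 2] += 0.35
            frames.append(Frame(time=fr.time, coordinates=c, box=fr.box))
        shifted = Trajectory(frames=frames, topology=system)
        assert phosphorus_z_displacement(shifted, "upper", ALL) == \
            pytest.approx(base, abs=1e-12)

    def test_gaussian_jitter_rms_matches_sigma(self, pure_noisy):
        _, traj, _ = pure_noisy
        zd = phosphorus_z_displacement(traj, "upper", ALL)
        assert zd == pytest.approx(0.05, rel=0.10)


class TestThicknessMap:
    def test_flat_bilayer_uniform(self, pure_clean):
        _, traj, _ = pure_clean
        tm = thickness_map(traj, window=ALL)
        assert np.allclose(tm.values, 4.4, atol=1e-9)
        assert tm.defined.all()

    def test_dimple_recovered_within_tolerance(self):
        """Planted Gaussian dimple (0.8 nm) recovered within 0.1 nm per
        cell at jitter 0.02, 50 frames."""
        params = preset("pure", seed=31, n_frames=50, jitter_sigma=0.02)
        params.dimple = Dimple(amplitude=0.8, width=1.2, center=(2.5, 3.5))
        _, traj, truth = generate_system(params)
        tm = thickness_map(traj, window=ALL)
        assert tm.values.shape == truth.thickness_field.shape
        assert np.nanmax(np.abs(tm.values - truth.thickness_field)) < 0.1
        # the dimple actually thins the planted field
        assert np.nanmin(truth.thickness_field) < 4.4 - 0.5

    def test_infinite_radius_gives_mean_separation(self, pure_noisy):
        system, traj, _ = pure_noisy
        tm = thickness_map(traj, smoothing_radius=100.0,
                           grid_spacing=1.0, window=ALL)
        spread = np.nanmax(tm.values) - np.nanmin(tm.values)
        assert spread < 1e-9
        p = system.lipid_phosphorus_indices()
        seps = []
        for fr in traj.frames:
            z = fr.coordinates[p, 2]
            seps.append(z[z > 0].mean() - z[z < 0].mean())
        assert np.nanmean(tm.values) == pytest.approx(np.mean(seps),
                                                      abs=1e-9)

    def test_matches_naive_reference(self):
        params = preset("pure", seed=32, n_frames=3, jitter_sigma=0.05)
        params.n_lipids_per_leaflet = 8
        _, traj, _ = generate_system(params)
        w = ALL
        tm = thickness_map(traj, grid_spacing=1.0, smoothing_radius=1.5,
                           window=w)
        ref = naive_thickness(traj, 1.0, 1.5, w)
        both = ~np.isnan(ref)
        assert np.array_equal(both, tm.defined)
        assert np.nanmax(np.abs(tm.values[both] - ref[both])) < 1e-9

    def test_parameter_validation(self, pure_clean):
        _, traj, _ = pure_clean
        with pytest.raises(ValueError):
            thickness_map(traj, grid_spacing=-1.0)
        with pytest.raises(ValueError):
            thickness_map(traj, smoothing_radius=0.0)
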