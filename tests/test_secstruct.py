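"""Kabsch-Sander hydrogen bonds, structure assignment and helix content,
cross-checked against an independent DSSP implementation (mdtraj)."""

import numpy as np
import pytest

from memperturb.generate import (
    GeneratorParams,
    generate_system,
    ideal_helix,
    _mdtraj_topology,
)
from memperturb.secstruct import (
    assign_secondary_structure,
    helix_content,
    ks_hbond_energy,
    secondary_structure_profile,
)
from memperturb.system import Frame, TimeWindow, Trajectory

ALL = TimeWindow(-1.0, 1e9)


def _helix_system(helix_window=None, n_frames=1, seed=61, jitter=0.0,
                  length=37):
    params = GeneratorParams(n_peptides=1, peptide_depth=3.0,
                             peptide_tilt=0.0, peptide_length=length,
                             helix_window=helix_window, n_frames=n_frames,
                             jitter_sigma=jitter, seed=seed)
    return generate_system(params)


def _mdtraj_codes(system, frame):
    import mdtraj as md

    top = _mdtraj_topology(system)
    t = md.Trajectory(xyz=frame.coordinates[None].astype(np.float32),
                      topology=top)
    codes = md.compute_dssp(t, simplified=False)[0]
    n_pep = sum(1 for a in top.atoms if a.residue.name != "POPG")
    n_res = sum(1 for r in top.residues if r.name != "POPG")
    return np.array([c if c != " " else "C" for c in codes[:n_res]])


class TestHBondEnergy:
    def test_helical_i_i4_bond_exists(self):
        """On a canonical helix the C=O(i)...H-N(i+4) energy is below the
        −0.5 kcal/mol bond threshold."""
        system, traj, _ = _helix_system()
        frame = traj.frames[0]
        res = system.chain_residues("A")

        def atom(ridx, name):
            idx = res[ridx]
            return frame.coordinates[
                idx[list(system.names[idx]).index(name)]]

        from memperturb.secstruct import _amide_hydrogens, _chain_backbone
        bb = _chain_backbone(frame, system, "A")
        h = _amide_hydrogens(bb)
        for i in (5, 10, 20):
            e = ks_hbond_energy(atom(i, "C"), atom(i, "O"),
                                atom(i + 4, "N"), h[i + 4])
            assert e < -0.5

    def test_distant_pair_has_negligible_energy(self):
        c = np.array([0.0, 0.0, 0.0])
        o = np.array([0.0, 0.0, 0.123])
        n = np.array([2.0, 0.0, 0.0])  # 20 angstrom away
        h = n + np.array([0.0, 0.0, 0.1])
        assert abs(ks_hbond_energy(c, o, n, h)) < 0.5

    def test_symmetric_placement_cancels(self):
        """r_ON = r_OH and r_CH = r_CN makes the four 1/r terms cancel."""
        c = np.array([0.0, 0.0, 0.0])
        o = np.array([1.0, 0.0, 0.0])
        # N and H both equidistant from the O and from the C respectively
        n = np.array([0.5, 1.0, 0.0])
        h = np.array([0.5, -1.0, 0.0])
        assert ks_hbond_energy(c, o, n, h) == pytest.approx(0.0, abs=1e-12)

    def test_clash_is_no_bond(self):
        c = np.array([0.0, 0.0, 0.0])
        o = np.array([0.0, 0.0, 0.002])  # 0.02 angstrom from C
        n = np.array([0.0, 0.0, 0.004])
        h = np.array([0.0, 0.0, 0.006])
        assert ks_hbond_energy(c, o, n, h) == 0.0


class TestAssignment:
    def test_ideal_helix_interior_is_helical(self):
        system, traj, _ = _helix_system()
        codes = assign_secondary_structure(traj.frames[0], system)["A"]
        assert (codes == "H").sum() >= 30
        assert np.all(codes[2:35] == "H")

    def test_extended_chain_has_no_helix(self):
        system, traj, _ = _helix_system(helix_window=(1, 2))
        codes = assign_secondary_structure(traj.frames[0], system)["A"]
        assert (codes == "H").sum() == 0

    def test_scrambled_coordinates_are_coil(self):
        system, traj, _ = _helix_system()
        rng = np.random.default_rng(0)
        frame = traj.frames[0]
        pep = system.chain_atoms("A")
        coords = frame.coordinates.copy()
        coords[pep] = rng.uniform(0, 5, size=(pep.size, 3))
        scrambled = Frame(time=0.0, coordinates=coords, box=frame.box)
        codes = assign_secondary_structure(scrambled, system)["A"]
        assert not np.isin(codes, ["H", "G", "I", "E"]).any()

    def test_rigid_transform_invariance(self):
        system, traj, _ = _helix_system()
        frame = traj.frames[0]
        base = assign_secondary_structure(frame, system)["A"]
        ang = np.radians(29.0)
        rot = np.array([[1, 0, 0],
                        [0, np.cos(ang), -np.sin(ang)],
                        [0, np.sin(ang), np.cos(ang)]])
        coords = frame.coordinates @ rot.T + np.array([1.0, -2.0, 3.0])
        moved = Frame(time=0.0, coordinates=coords, box=frame.box)
        assert np.array_equal(
            assign_secondary_structure(moved, system)["A"], base)

    @pytest.mark.parametrize("window", [None, (1, 2), (9, 29)])
    def test_agrees_with_reference_dssp(self, window):
        """≥ 95% residue-level agreement with mdtraj's DSSP on helix,
        extended and partial-helix fixtures."""
        system, traj, _ = _helix_system(helix_window=window)
        ours = assign_secondary_structure(traj.frames[0], system)["A"]
        ref = _mdtraj_codes(system, traj.frames[0])
        agreement = float(np.mean(ours == ref))
        assert agreement >= 0.95


class TestHelixContent:
    def test_rigid_trajectory_has_zero_sd(self):
        _, traj, _ = _helix_system(n_frames=4, jitter=0.05)
        hc = helix_content(traj, ALL)
        assert hc.sd == pytest.approx(0.0, abs=1e-12)

    def test_two_state_statistics(self):
        """Alternating helical and scrambled frames give mean = (f1+f2)/2
        and sd = |f1−f2|/2 of the per-frame helical fractions."""
        system, traj, _ = _helix_system(n_frames=2)
        rng = np.random.default_rng(1)
        pep = system.chain_atoms("A")
        f2 = traj.frames[1]
        coords = f2.coordinates.copy()
        coords[pep] = rng.uniform(0, 5, size=(pep.size, 3))
        mixed = Trajectory(frames=[traj.frames[0],
                                   Frame(time=f2.time, coordinates=coords,
                                         box=f2.box)], topology=system)
        prof = secondary_structure_profile(mixed, ALL)
        frac = 100.0 * np.isin(prof.codes, ["H", "G", "I"]).mean(axis=1)
        hc = helix_content(mixed, ALL)
        assert hc.mean == pytest.approx((frac[0] + frac[1]) / 2, abs=1e-9)
        assert hc.sd == pytest.approx(abs(frac[0] - frac[1]) / 2, abs=1e-9)
        assert frac[1] == 0.0

    def test_planted_19_of_37_content(self):
        """A 19-residue planted helix in a 37-residue chain yields
        19/37 ≈ 51.4% helical content."""
        _, traj, truth = _helix_system(helix_window=(10, 28), n_frames=4,
                                       jitter=0.02)
        assert len(truth.helix_residues["A"]) == 19
        hc = helix_content(traj, ALL, codes={"H"})
        assert hc.mean == pytest.approx(100.0 * 19 / 37, abs=2.0)

    def test_bounds_and_code_set(self):
        _, traj, _ = _helix_system(n_frames=2)
        hc = helix_content(traj, ALL, codes={"H"})
        assert 0.0 <= hc.mean <= 100.0
        strict = helix_content(traj, ALL, codes={"H"})
        broad = helix_content(traj, ALL, codes={"H", "G", "I"})
        assert broad.mean >= strict.mean
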