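"""Nonbonded pair energies and the per-residue / head-tail decompositions."""

import numpy as np
import pytest

from memperturb.energetics import (
    NonbondedOptions,
    group_energy_split,
    nonbonded_pair_energy,
    residue_lipid_energy_profile,
)
from memperturb.generate import generate_system, preset
from memperturb.system import (
    COULOMB_CONSTANT,
    Frame,
    System,
    TimeWindow,
    Trajectory,
    min_image_displacement,
)

ALL = TimeWindow(-1.0, 1e9)


def naive_residue_energies(traj, window, options):
    """Reference: plain double loop over (peptide atom, lipid atom) pairs."""
    system = traj.topology
    pep = np.flatnonzero(system.molecule_kind == "peptide")
    lip = np.flatnonzero(system.molecule_kind == "lipid")
    n_lipids = len(np.unique(system.molecule_index[lip]))
    frames = window.select(traj)
    acc = {}
    for fi in frames:
        fr = traj.frames[fi]
        for i in pep:
            key = (str(system.chain_id[i]), int(system.residue_index[i]))
            e_acc, v_acc = acc.get(key, (0.0, 0.0))
            for j in lip:
                d = fr.coordinates[i] - fr.coordinates[j]
                d = min_image_displacement(d, fr.box)
                r = float(np.sqrt((d * d).sum()))
                e, v = nonbonded_pair_energy(
                    (system.charge[i], system.c6[i], system.c12[i]),
                    (system.charge[j], system.c6[j], system.c12[j]),
                    r, options)
                e_acc += e
                v_acc += v
            acc[key] = (e_acc, v_acc)
    norm = 1.0 / (len(frames) * n_lipids)
    return {k: (e * norm, v * norm) for k, (e, v) in acc.items()}


class TestPairEnergy:
    def test_coulomb_constant_definition(self):
        e, v = nonbonded_pair_energy((1.0, 0, 0), (1.0, 0, 0), 1.0)
        assert e == pytest.approx(138.935485, abs=1e-9)
        assert v == 0.0

    def test_lj_zero_crossing(self):
        c6, c12 = 4.0e-3, 4.0e-6
        r0 = (c12 / c6) ** (1.0 / 6.0)
        _, v = nonbonded_pair_energy((0, c6, c12), (0, c6, c12), r0)
        assert v == pytest.approx(0.0, abs=1e-12)

    def test_between_cutoffs_only_vdw_survives(self):
        """At 1.3 nm the 1.2 nm Coulomb term is cut but the 1.4 nm vdW
        term is not."""
        c6, c12 = 4.0e-3, 4.0e-6
        e, v = nonbonded_pair_energy((1.0, c6, c12), (1.0, c6, c12), 1.3)
        assert e == 0.0
        assert v != 0.0

    def test_overlap_errors(self):
        with pytest.raises(ValueError):
            nonbonded_pair_energy((1, 0, 0), (1, 0, 0), 0.0)

    def test_combination_rules_agree_for_identical_atoms(self):
        c6, c12 = 3.0e-3, 5.0e-6
        lb = NonbondedOptions(combination_rule="lorentz-berthelot")
        e1 = nonbonded_pair_energy((0, c6, c12), (0, c6, c12), 0.5)
        e2 = nonbonded_pair_energy((0, c6, c12), (0, c6, c12), 0.5, lb)
        assert e1[1] == pytest.approx(e2[1], rel=1e-9)


def _single_pair_system():
    """One +1 peptide pseudo-atom 1 nm above one −1 lipid head atom."""
    system = System(
        names=np.array(["CB", "P"], dtype=object),
        elements=np.array(["C", "P"], dtype=object),
        residue_index=np.array([0, 1]),
        residue_name=np.array(["LYS", "POPG"], dtype=object),
        chain_id=np.array(["A", ""], dtype=object),
        molecule_kind=np.array(["peptide", "lipid"], dtype=object),
        molecule_index=np.array([0, 1]),
        charge=np.array([1.0, -1.0]),
        c6=np.zeros(2), c12=np.zeros(2),
        lipid_group=np.array(["none", "head"], dtype=object),
    )
    frame = Frame(time=0.0,
                  coordinates=np.array([[2.0, 2.0, 3.0], [2.0, 2.0, 2.0]]),
                  box=np.array([5.0, 7.0, 9.0]))
    return Trajectory(frames=[frame], topology=system)


class TestDecomposition:
    def test_single_pair_coulomb(self):
        dec = residue_lipid_energy_profile(_single_pair_system(), ALL)
        assert dec.per_residue["elec_kj_per_mol_per_lipid"].iloc[0] == \
            pytest.approx(-COULOMB_CONSTANT, abs=1e-9)
        assert dec.per_residue["vdw_kj_per_mol_per_lipid"].iloc[0] == 0.0

    def test_null_charges_give_zero(self):
        traj = _single_pair_system()
        traj.topology.charge[:] = 0.0
        dec = residue_lipid_energy_profile(traj, ALL)
        assert np.allclose(dec.per_residue[
            ["elec_kj_per_mol_per_lipid", "vdw_kj_per_mol_per_lipid"]], 0.0)

    def test_matches_brute_force(self):
        params = preset("1mono", seed=51, n_frames=2, jitter_sigma=0.05)
        params.n_lipids_per_leaflet = 4
        params.tail_carbons = 4
        _, traj, _ = generate_system(params)
        opts = NonbondedOptions()
        dec = residue_lipid_energy_profile(traj, ALL, opts)
        ref = naive_residue_energies(traj, ALL, opts)
        for _, row in dec.per_residue.iterrows():
            # reference keys use global residue indices
            key = next(k for k in ref
                       if k[0] == row["chain"]
                       and k[1] == row["residue"] - 1)
            assert row["elec_kj_per_mol_per_lipid"] == pytest.approx(
                ref[key][0], abs=1e-9)
            assert row["vdw_kj_per_mol_per_lipid"] == pytest.approx(
                ref[key][1], abs=1e-9)

    def test_residue_and_group_sums_conserve_total(self, mono_clean):
        _, traj, _ = mono_clean
        dec = residue_lipid_energy_profile(traj, ALL)
        res_e = dec.per_residue["elec_kj_per_mol_per_lipid"].sum()
        res_v = dec.per_residue["vdw_kj_per_mol_per_lipid"].sum()
        he, hv = dec.head["A"]
        te, tv = dec.tail["A"]
        assert res_e == pytest.approx(he + te, rel=1e-9, abs=1e-9)
        assert res_v == pytest.approx(hv + tv, rel=1e-9, abs=1e-9)

    def test_tail_elec_zero_when_charge_on_heads_only(self, mono_clean):
        """Generator lipids carry charge on the phosphorus head atom only."""
        _, traj, _ = mono_clean
        dec = group_energy_split(traj, ALL)
        assert dec.tail["A"][0] == pytest.approx(0.0, abs=1e-12)
        assert dec.head["A"][0] < 0  # cationic peptide, anionic heads

    def test_system_doubling_preserves_per_lipid_residue_values(self):
        """Duplicating peptide+lipids at a far offset doubles both the pair
        sums and the lipid count, so the chain-aggregated per-residue
        per-lipid energies are unchanged."""
        params = preset("1mono", seed=52, n_frames=1, jitter_sigma=0.0)
        params.n_lipids_per_leaflet = 4
        params.tail_carbons = 4
        _, traj, _ = generate_system(params)
        base = residue_lipid_energy_profile(traj, ALL)

        system = traj.topology
        frame = traj.frames[0]
        # copy along z so in-plane minimum imaging is untouched; the z
        # separation is far outside both cutoffs
        shift = np.array([0.0, 0.0, 50.0])
        coords = np.vstack([frame.coordinates, frame.coordinates + shift])
        nmol = system.molecule_index.max() + 1
        nres = system.residue_index.max() + 1
        copy_chain = np.where(system.chain_id == "A", "B",
                              system.chain_id).astype(object)
        dup = System(
            names=np.tile(system.names, 2),
            elements=np.tile(system.elements, 2),
            residue_index=np.concatenate(
                [system.residue_index, system.residue_index + nres]),
            residue_name=np.tile(system.residue_name, 2),
            chain_id=np.concatenate([system.chain_id, copy_chain]),
            molecule_kind=np.tile(system.molecule_kind, 2),
            molecule_index=np.concatenate(
                [system.molecule_index, system.molecule_index + nmol]),
            charge=np.tile(system.charge, 2),
            c6=np.tile(system.c6, 2),
            c12=np.tile(system.c12, 2),
            lipid_group=np.tile(system.lipid_group, 2),
        )
        doubled = Trajectory(
            frames=[Frame(time=0.0, coordinates=coords,
                          box=np.array([5.0, 7.0, 100.0]))],
            topology=dup)
        got = residue_lipid_energy_profile(doubled, ALL)
        summed = got.per_residue.groupby("residue")[
            "elec_kj_per_mol_per_lipid"].sum().sort_index()
        ref = base.per_residue.set_index("residue")[
            "elec_kj_per_mol_per_lipid"].sort_index()
        assert np.allclose(summed.values, ref.values, atol=1e-9)

    def test_unlabeled_lipid_atom_errors(self):
        traj = _single_pair_system()
        traj.topology.lipid_group[1] = "none"
        with pytest.raises(ValueError, match="head/tail"):
            group_energy_split(traj, ALL)
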