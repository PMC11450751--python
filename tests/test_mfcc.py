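"""The capped-fragment decomposition: quartets, backends, the additivity
identity, and subsystem export."""

import numpy as np
import pandas as pd
import pytest

from epitope_decomp import (
    BackendConfig,
    ClassicalBackend,
    TableBackend,
    ToyComplexSpec,
    build_quartet,
    combine,
    enumerate_pairs,
    export_subsystems,
    interface_energies,
    make_toy_complex,
    pair_energy,
    read_pdb,
    total_energy,
)
from epitope_decomp.errors import ConfigError, MissingEnergyError
from epitope_decomp.mfcc import FILL_BOND_LENGTH, pair_id
from epitope_decomp.structures import Atom, Residue, ResidueRef, Structure
from epitope_decomp.synthetic import build_ideal_chain, random_charges


def _two_chain(n=5, gap=10.0):
    structure, _ = make_toy_complex(ToyComplexSpec(n_res_per_chain=n, gap=gap))
    return structure


class TestEnumeratePairs:
    def test_all_within_cutoff(self):
        structure = _two_chain(3)
        pairs = enumerate_pairs(structure, ["A"], ["B"], cutoff=50.0)
        assert len(pairs) == 9

    def test_far_pair_excluded(self):
        structure = _two_chain(2, gap=20.0)
        assert enumerate_pairs(structure, ["A"], ["B"], cutoff=8.0) == []

    def test_zero_cutoff_empty(self):
        structure = _two_chain(3)
        assert enumerate_pairs(structure, ["A"], ["B"], cutoff=0.0) == []

    def test_deterministic_order(self):
        structure = _two_chain(3)
        pairs = enumerate_pairs(structure, ["A"], ["B"], cutoff=50.0)
        keys = [(a.seq_number, b.seq_number) for a, b, _ in pairs]
        assert keys == sorted(keys)

    def test_group_overlap_rejected(self):
        structure = _two_chain(3)
        with pytest.raises(ConfigError):
            enumerate_pairs(structure, ["A"], ["A", "B"])


class TestQuartet:
    def test_central_pair_capping(self):
        structure = _two_chain(3)
        pair = (structure.chain("A")[1].ref, structure.chain("B")[1].ref)
        quartet = build_quartet(structure, pair)
        # S1 has both cores, S4 is caps-only
        s1_names = {r.ref.res_name for r in quartet.s1.residues}
        assert len(quartet.s1.residues) == 6
        assert len(quartet.s4.residues) == 4
        assert s1_names  # caps plus cores present
        core_keys = {pair[0].key, pair[1].key}
        assert not core_keys & {r.ref.key for r in quartet.s4.residues}

    def test_fill_hydrogen_count_equals_cut_bonds(self):
        structure = _two_chain(5)
        pair = (structure.chain("A")[2].ref, structure.chain("B")[2].ref)
        quartet = build_quartet(structure, pair)

        def fills(system):
            return sum(a.is_fill for _, a in system.iter_atoms())

        # with cores: two outer cuts per fragment; caps-only fragments add
        # two inner cuts each
        assert fills(quartet.s1) == 4
        assert fills(quartet.s2) == 6
        assert fills(quartet.s3) == 6
        assert fills(quartet.s4) == 8

    def test_fill_hydrogen_geometry(self):
        structure = _two_chain(5)
        chain = structure.chain("A")
        pair = (chain[2].ref, structure.chain("B")[2].ref)
        quartet = build_quartet(structure, pair)
        cap = next(r for r in quartet.s1.residues if r.ref.key == chain[1].ref.key)
        fill = next(a for a in cap.atoms if a.is_fill)
        anchor = cap.atom("N").coords
        assert np.linalg.norm(fill.coords - anchor) == pytest.approx(FILL_BOND_LENGTH)
        # placed along the former bond vector toward the excised neighbour
        prev_c = chain[0].atom("C").coords
        cos = np.dot(fill.coords - anchor, prev_c - anchor) / (
            FILL_BOND_LENGTH * np.linalg.norm(prev_c - anchor))
        assert cos == pytest.approx(1.0)

    def test_terminal_residue_single_cap(self):
        structure = _two_chain(3)
        pair = (structure.chain("A")[0].ref, structure.chain("B")[1].ref)
        quartet = build_quartet(structure, pair)
        frag_i_res = [r for r in quartet.s1.residues if r.ref.chain_id == "A"]
        assert len(frag_i_res) == 2  # core + single C-side cap

    def test_same_chain_pair_rejected(self):
        structure = _two_chain(3)
        chain = structure.chain("A")
        with pytest.raises(ConfigError):
            build_quartet(structure, (chain[0].ref, chain[1].ref))

    def test_water_follows_its_core(self):
        structure = _two_chain(5)
        ri = structure.chain("A")[2]
        water_pos = ri.atom("CA").coords + np.array([0.0, 0.0, 2.0])
        structure.add_residue(Residue(
            ResidueRef("A", 900, "", "HOH"),
            [Atom("O", "O", water_pos)], het=True))
        pair = (ri.ref, structure.chain("B")[2].ref)
        quartet = build_quartet(structure, pair, water_shell=2.5)
        assert quartet.n_waters == 1

        def has_water(system):
            return any(r.is_water for r in system.residues)

        assert has_water(quartet.s1) and has_water(quartet.s2)
        assert not has_water(quartet.s3) and not has_water(quartet.s4)


class TestCombine:
    def test_zero(self):
        assert combine(0, 0, 0, 0) == 0

    def test_four_term_formula(self):
        assert combine(-10, -4, -3, -1) == -4

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            combine(np.nan, 0, 0, 0)


class TestClassicalBackend:
    def test_coulomb_closed_form_through_quartet(self):
        # two unit charges 5 Å apart with eps=40: 332.0636/(40*5) kcal/mol
        a = Residue(ResidueRef("A", 1, "", "GLY"),
                    [Atom("CA", "C", np.array([0.0, 0.0, 0.0]))])
        b = Residue(ResidueRef("B", 1, "", "GLY"),
                    [Atom("CA", "C", np.array([5.0, 0.0, 0.0]))])
        structure = Structure([a, b])
        backend = ClassicalBackend(
            dielectric=40.0, charge_fn=lambda ref, name: 1.0, lj=False)
        record = pair_energy(structure, (a.ref, b.ref), backend)
        assert record.energy == pytest.approx(332.0636 / (40 * 5), rel=1e-9)

    def test_lj_negligible_at_20_angstroms(self):
        chain_a = build_ideal_chain("A", ["GLY"] * 3)
        chain_b = build_ideal_chain("B", ["GLY"] * 3, origin=(0.0, 20.0, 0.0))
        structure = Structure(chain_a + chain_b)
        backend = ClassicalBackend(charge_fn=lambda ref, name: 0.0)
        record = pair_energy(
            structure, (chain_a[1].ref, chain_b[1].ref), backend)
        assert abs(record.energy) < 1e-3

    def test_dielectric_validation(self):
        with pytest.raises(ConfigError):
            ClassicalBackend(dielectric=0.0)


class TestMfccIdentity:
    def test_equals_direct_pair_energy_random_charges(self, rng):
        for trial in range(5):
            base, _ = make_toy_complex(ToyComplexSpec(n_res_per_chain=4, seed=trial))
            charges = random_charges(base, rng)
            structure, truth = make_toy_complex(
                ToyComplexSpec(n_res_per_chain=4, charge_assignment=charges,
                               seed=trial))
            records = interface_energies(structure, ["A"], ["B"],
                                         truth.backend, cutoff=50.0)
            for record in records:
                assert record.energy == pytest.approx(
                    truth.pair_energies[record.pair], abs=1e-9)

    def test_total_is_brute_force_double_sum(self, rng):
        base, _ = make_toy_complex(ToyComplexSpec(n_res_per_chain=4))
        charges = random_charges(base, rng)
        structure, truth = make_toy_complex(
            ToyComplexSpec(n_res_per_chain=4, charge_assignment=charges))
        records = interface_energies(structure, ["A"], ["B"],
                                     truth.backend, cutoff=50.0)
        brute = sum(truth.pair_energies.values())
        assert total_energy(records) == pytest.approx(brute, abs=1e-8)

    def test_cutoff_monotonicity(self):
        structure, truth = make_toy_complex(ToyComplexSpec(
            n_res_per_chain=4, gap=6.0))
        wide = {r.pair for r in interface_energies(
            structure, ["A"], ["B"], truth.backend, cutoff=8.0)}
        narrow = {r.pair for r in interface_energies(
            structure, ["A"], ["B"], truth.backend, cutoff=6.5)}
        assert narrow <= wide

    def test_empty_interface(self):
        structure, truth = make_toy_complex(ToyComplexSpec(
            n_res_per_chain=2, gap=30.0))
        records = interface_energies(structure, ["A"], ["B"],
                                     truth.backend, cutoff=8.0)
        assert records == [] and total_energy(records) == 0.0


class TestTableBackend:
    def test_pass_through_reproduces_combine(self, tmp_path):
        structure = _two_chain(3)
        pair = (structure.chain("A")[1].ref, structure.chain("B")[1].ref)
        pid = pair_id(pair)
        frame = pd.DataFrame({
            "pair_id": [pid] * 4,
            "subsystem": ["S1", "S2", "S3", "S4"],
            "energy_kcal_mol": [-10.0, -4.0, -3.0, -1.0],
        })
        csv = tmp_path / "energies.csv"
        frame.to_csv(csv, index=False)
        backend = BackendConfig(kind="table", table_path=str(csv)).resolve()
        record = pair_energy(structure, pair, backend)
        assert record.energy == -4.0
        assert record.backend_id == "table"

    def test_missing_entry_names_subsystem(self, tmp_path):
        structure = _two_chain(3)
        pair = (structure.chain("A")[1].ref, structure.chain("B")[1].ref)
        frame = pd.DataFrame({
            "pair_id": [pair_id(pair)] * 3,
            "subsystem": ["S1", "S2", "S3"],
            "energy_kcal_mol": [0.0, 0.0, 0.0],
        })
        backend = TableBackend(frame)
        with pytest.raises(MissingEnergyError, match="S4"):
            pair_energy(structure, pair, backend)


class TestExport:
    @pytest.mark.parametrize("fmt", ["pdb", "xyz"])
    def test_four_files_with_matching_atom_counts(self, tmp_path, fmt):
        structure = _two_chain(5)
        pair = (structure.chain("A")[2].ref, structure.chain("B")[2].ref)
        quartet = build_quartet(structure, pair)
        paths = export_subsystems(quartet, tmp_path, format=fmt)
        assert len(paths) == 4 and all(p.exists() for p in paths)
        for path, (_, system) in zip(paths, quartet.subsystems()):
            if fmt == "xyz":
                n = int(path.read_text().splitlines()[0])
            else:
                n = len(read_pdb(path)[0])
            assert n == len(system)

    def test_pdb_round_trip_coordinates(self, tmp_path):
        structure = _two_chain(5)
        pair = (structure.chain("A")[2].ref, structure.chain("B")[2].ref)
        quartet = build_quartet(structure, pair)
        (p1, *_rest) = export_subsystems(quartet, tmp_path, format="pdb")
        (back,) = read_pdb(p1)
        np.testing.assert_allclose(
            back.coord_array(), quartet.s1.coord_array(), atol=5e-4)

    def test_export_backend_not_an_energy_source(self):
        with pytest.raises(ConfigError):
            BackendConfig(kind="export").resolve()
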