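"""Peptide design operations and the sequence-based property panel.

The printed reference values for the eight CDR-derived mimetic peptides
(molecular weight, pI, net charge, protease susceptibility) live in
test_acceptance.py; here the operations are checked against independent
oracles: Biopython's ProtParam implementation for MW/pI, the pyteomics
ExPASy regular-expression rules for internal cleavage sites, and closed
forms / brute-force scans for the rest.
"""

import numpy as np
import pytest
import re
from hypothesis import given, settings, strategies as st

from Bio.SeqUtils.ProtParam import ProteinAnalysis
from pyteomics.parser import expasy_rules

from epitope_decomp import (
    CleavageRuleSet,
    PeptideRecord,
    RegionDef,
    cleavage_sites,
    cyclize,
    design_report,
    extract_segment,
    isoelectric_point,
    molecular_weight,
    mutate,
    net_charge,
)
from epitope_decomp.errors import ConfigError, MissingResidueError, SequenceError
from epitope_decomp.peptides import WATER_MASS, charge_at_ph
from epitope_decomp.structures import Structure

AA = "ACDEFGHIKLMNPQRSTVWY"
sequences = st.text(alphabet=AA, min_size=1, max_size=30)


class TestExtractSegment:
    def test_hcdr2_segment(self, antibody_like):
        rec = extract_segment(antibody_like, RegionDef("HCDR2", "H", ((50, 60),)))
        assert rec.sequence == "VIWFDGTKKYY"
        assert not rec.cyclic and rec.source.name == "HCDR2"

    def test_lcdr3_segment(self, antibody_like):
        rec = extract_segment(antibody_like, RegionDef("LCDR3", "L", ((90, 96),)))
        assert rec.sequence == "QSYSTPL"

    def test_single_residue_region(self, antibody_like):
        rec = extract_segment(antibody_like, RegionDef("one", "H", ((50, 50),)))
        assert rec.sequence == "V"

    def test_gap_raises(self, antibody_like):
        gapped = Structure([
            r for r in antibody_like.residues
            if not (r.ref.chain_id == "H" and r.ref.seq_number == 55)
        ])
        with pytest.raises(MissingResidueError, match="H:55"):
            extract_segment(gapped, RegionDef("HCDR2", "H", ((50, 60),)))


class TestMutate:
    def test_s91y_on_lcdr3(self, antibody_like):
        rec = extract_segment(antibody_like, RegionDef("LCDR3", "L", ((90, 96),)))
        mut = mutate(rec, 91, "Y")
        assert mut.sequence == "QYYSTPL"
        assert mut.mutations == ((91, "S", "Y"),)

    def test_identity_mutation_logged(self, antibody_like):
        rec = extract_segment(antibody_like, RegionDef("LCDR3", "L", ((90, 96),)))
        same = mutate(rec, 91, "S")
        assert same.sequence == rec.sequence
        assert same.mutations == ((91, "S", "S"),)

    def test_out_of_range_position(self, antibody_like):
        rec = extract_segment(antibody_like, RegionDef("LCDR3", "L", ((90, 96),)))
        with pytest.raises(ConfigError):
            mutate(rec, 80, "Y")

    def test_sequence_only_record_uses_index(self):
        rec = PeptideRecord("p", "QSYSTPL")
        assert mutate(rec, 2, "Y").sequence == "QYYSTPL"


class TestCyclize:
    @pytest.mark.parametrize("seq, expected", [
        ("QSYSTPL", "CQSYSTPLC"),
        ("GIGARRGPY", "CGIGARRGPYC"),
    ])
    def test_terminal_cysteines(self, seq, expected):
        cyc = cyclize(PeptideRecord("p", seq))
        assert cyc.sequence == expected and cyc.cyclic

    def test_double_cyclization_rejected(self):
        cyc = cyclize(PeptideRecord("p", "QSYSTPL"))
        with pytest.raises(SequenceError):
            cyclize(cyc)

    def test_mass_increment_is_two_cysteines(self):
        seq = "GIGARRGPY"
        assert molecular_weight("C" + seq + "C") == pytest.approx(
            molecular_weight(seq) + 2 * 103.1388, abs=1e-6)


class TestMolecularWeight:
    def test_glycine(self):
        assert molecular_weight("G") == pytest.approx(75.07, abs=0.005)

    @given(sequences)
    @settings(max_examples=40, deadline=None)
    def test_matches_protparam_oracle(self, seq):
        # Biopython uses a slightly different average-mass table; agreement
        # is within hundredths of a Dalton per residue
        oracle = ProteinAnalysis(seq).molecular_weight()
        assert molecular_weight(seq) == pytest.approx(
            oracle, abs=0.002 * len(seq) + 0.02)

    @given(sequences, sequences)
    @settings(max_examples=25, deadline=None)
    def test_additivity(self, s1, s2):
        assert molecular_weight(s1 + s2) == pytest.approx(
            molecular_weight(s1) + molecular_weight(s2) - WATER_MASS, abs=1e-6)

    def test_invalid_letter(self):
        with pytest.raises(SequenceError):
            molecular_weight("GXZ")


class TestIsoelectricPoint:
    @given(sequences)
    @settings(max_examples=40, deadline=None)
    def test_matches_biopython_oracle(self, seq):
        from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint
        from hypothesis import assume

        oracle = IsoelectricPoint(seq).pi()
        # Biopython clamps its bisection bracket at pH 4.05; below that it
        # cannot follow the charge function, so compare only above the clamp
        assume(oracle > 4.10)
        assert isoelectric_point(seq) == pytest.approx(oracle, abs=0.01)

    @given(sequences)
    @settings(max_examples=30, deadline=None)
    def test_charge_at_pi_is_zero(self, seq):
        assert charge_at_ph(seq, isoelectric_point(seq)) == pytest.approx(
            0.0, abs=0.01)

    def test_termini_only_peptide_is_midpoint(self):
        # glycine oligomer: only the termini titrate, so the pI is the
        # midpoint of the terminal pKas (7.5 and 3.55)
        assert isoelectric_point("GGGG") == pytest.approx(
            (7.5 + 3.55) / 2, abs=0.01)


class TestNetCharge:
    @pytest.mark.parametrize("seq, expected", [
        ("GIGARRGPY", +2),
        ("GGG", 0),
        ("DKEKR", +1),
        ("VIWFDGTKKYY", +1),  # His/termini excluded by convention
        ("HHH", 0),
    ])
    def test_counting_convention(self, seq, expected):
        assert net_charge(seq) == expected


class TestCleavageSites:
    def test_trypsin_examples(self):
        assert cleavage_sites("GIGARRGPY", "trypsin")[0] == 2
        # K before P blocked, the second K cleaves
        count, sites = cleavage_sites("AKPAKA", "trypsin")
        assert (count, sites) == (1, [5])

    def test_resistant_sequence(self):
        for enzyme in CleavageRuleSet().enzymes():
            assert cleavage_sites("GGGG", enzyme)[0] == 0

    def test_unknown_enzyme(self):
        with pytest.raises(ConfigError):
            cleavage_sites("GGGG", "papain")

    def test_terminal_counting_toggle(self):
        permissive = CleavageRuleSet()
        strict = CleavageRuleSet(terminal_counting=False)
        assert cleavage_sites("VIWFDGTKKYY", "chymotrypsin_high", permissive)[0] == 4
        assert cleavage_sites("VIWFDGTKKYY", "chymotrypsin_high", strict)[0] == 3

    @pytest.mark.parametrize("enzyme, expasy_key", [
        ("chymotrypsin_high", "chymotrypsin high specificity"),
        ("chymotrypsin_low", "chymotrypsin low specificity"),
        ("pepsin_1.3", "pepsin ph1.3"),
        ("pepsin_gt2", "pepsin ph2.0"),
    ])
    def test_interior_sites_match_expasy_regex(self, enzyme, expasy_key, rng):
        # windows fully inside the sequence must agree with the published
        # ExPASy regular expressions (boundary conventions differ, so only
        # positions with a complete P3..P2' window are compared)
        pattern = re.compile(expasy_rules[expasy_key])
        for _ in range(60):
            seq = "".join(rng.choice(list(AA), size=12))
            _, sites = cleavage_sites(seq, enzyme)
            mine = {i for i in sites if 3 <= i <= len(seq) - 2}
            theirs = {
                m + 1 for m in range(len(seq))
                if pattern.match(seq, m) and 3 <= m + 1 <= len(seq) - 2
            }
            assert mine == theirs, seq


class TestDesignReport:
    def test_empty_input(self):
        frame = design_report([])
        assert len(frame) == 0 and "mw" in frame.columns

    def test_row_order_follows_input(self):
        peps = [PeptideRecord("b", "GIGARRGPY"), PeptideRecord("a", "QSYSTPL")]
        frame = design_report(peps)
        assert list(frame["name"]) == ["b", "a"]

    def test_panel_columns_present(self):
        frame = design_report([PeptideRecord("p", "QSYSTPL")])
        row = frame.iloc[0]
        assert row["mw"] == pytest.approx(794.86, abs=0.02)
        assert row["pi"] == pytest.approx(5.52, abs=0.01)
        assert row["net_charge"] == 0
        assert row["sites_trypsin"] == 0
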