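"""Variant expansion, anchored proteome scanning, and molecular weights."""

import io
import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orphan_enzymes.peptide_matcher import (
    AMINO_ACIDS,
    ErrorModel,
    MatchCandidate,
    NTerminalRead,
    ProteomeEntry,
    VariantCapError,
    check_mw,
    compute_mw,
    enumerate_variants,
    mw_only_match,
    parse_read,
    read_proteome_fasta,
    render_read,
    scan_proteome,
    validate_mw,
    write_proteome_fasta,
)

NO_MODEL = ErrorModel(cys_loss=False, deamidation=False, met_start=False)


class TestReadFormat:
    @pytest.mark.parametrize("text", ["ASG", "A{S|T}G", "MA{S|T}KXLD", "X{D|N}X"])
    def test_round_trip(self, text):
        assert render_read(parse_read(text)) == text

    def test_unknown_position_parsed(self):
        read = parse_read("AXG")
        assert read.positions[1] is None
        assert read.length == 3

    def test_bad_residue_rejected(self):
        with pytest.raises(ValueError):
            parse_read("A{S|Z}G")

    def test_unclosed_brace_rejected(self):
        with pytest.raises(ValueError):
            parse_read("A{S|T")

    def test_empty_read_rejected(self):
        with pytest.raises(ValueError):
            NTerminalRead(())


class TestEnumerateVariants:
    def test_two_way_ambiguity_product(self):
        variants = enumerate_variants(parse_read("A{S|T}G"), NO_MODEL)
        assert [v.sequence for v in variants] == ["ASG", "ATG"]

    def test_deamidation_admits_asparagine(self):
        variants = enumerate_variants(parse_read("AD"),
                                      ErrorModel(cys_loss=False, deamidation=True))
        assert {v.sequence for v in variants} == {"AD", "AN"}
        traced = next(v for v in variants if v.sequence == "AN")
        assert traced.corrections == ((1, "deamidation"),)

    def test_deamidation_admits_glutamine(self):
        variants = enumerate_variants(parse_read("E"),
                                      ErrorModel(cys_loss=False, deamidation=True))
        assert {v.sequence for v in variants} == {"E", "Q"}

    def test_two_ambiguous_positions_four_variants(self):
        variants = enumerate_variants(parse_read("A{S|T}G{D|H}K"), NO_MODEL)
        assert len(variants) == 4

    def test_unknown_expands_to_alphabet_plus_cysteine(self):
        model = ErrorModel(cys_loss=True, deamidation=False,
                           unknown_alphabet=frozenset("AG"))
        variants = enumerate_variants(parse_read("X"), model)
        assert {v.sequence for v in variants} == {"A", "C", "G"}
        cys = next(v for v in variants if v.sequence == "C")
        assert cys.corrections == ((0, "cys_loss"),)

    def test_count_conservation(self):
        read = parse_read("A{S|T}X{D|N}")
        model = ErrorModel(cys_loss=True, deamidation=True,
                           unknown_alphabet=frozenset("AGC"))
        expected = 1 * 2 * 3 * 2  # {S,T} x {A,C,G} x {D, N(deamidation)}
        assert len(enumerate_variants(read, model)) == expected

    def test_lexicographic_order(self):
        variants = enumerate_variants(parse_read("{T|S}{G|A}"), NO_MODEL)
        assert [v.sequence for v in variants] == ["SA", "SG", "TA", "TG"]

    def test_cap_overflow_reports_count(self):
        model = ErrorModel(variant_cap=100)
        with pytest.raises(VariantCapError, match="400"):
            enumerate_variants(parse_read("XX"), model)  # 20^2 = 400


def _brute_force_scan(variants, proteome, max_mismatch, max_start_offset, met_start):
    found = []
    for entry in proteome:
        offsets = set(range(max_start_offset + 1))
        if met_start and entry.sequence.startswith("M"):
            offsets.add(1)
        for variant in variants:
            for off in sorted(offsets):
                window = entry.sequence[off:off + len(variant.sequence)]
                if len(window) < len(variant.sequence):
                    continue
                mism = sum(a != b or b == "X"
                           for a, b in zip(variant.sequence, window))
                if mism <= max_mismatch:
                    found.append((entry.protein_id, off, mism, variant.sequence))
    return sorted(found)


class TestScanProteome:
    def _proteome(self, rng, n=10, length=60):
        return [ProteomeEntry(f"p{i:03d}", "org",
                              "".join(rng.choice(AMINO_ACIDS) for _ in range(length)))
                for i in range(n)]

    def test_exact_prefix_single_candidate(self):
        rng = random.Random(0)
        proteome = self._proteome(rng)
        target = proteome[3]
        variants = enumerate_variants(parse_read(target.sequence[:12]), NO_MODEL)
        cands = scan_proteome(variants, proteome, max_mismatch=0,
                              max_start_offset=0, met_start=False)
        assert len(cands) == 1
        assert (cands[0].protein_id, cands[0].start_offset, cands[0].mismatches) \
            == ("p003", 0, 0)

    def test_exact_scan_equals_prefix_search(self):
        rng = random.Random(1)
        proteome = self._proteome(rng, n=30)
        for entry in proteome:
            variants = enumerate_variants(parse_read(entry.sequence[:15]), NO_MODEL)
            cands = scan_proteome(variants, proteome, max_mismatch=0,
                                  max_start_offset=0, met_start=False)
            oracle = {e.protein_id for e in proteome
                      if e.sequence.startswith(entry.sequence[:15])}
            assert {c.protein_id for c in cands} == oracle

    def test_met_start_placement(self):
        proteome = [ProteomeEntry("p1", "org", "M" + "ACDEFGHIKLMN")]
        variants = enumerate_variants(parse_read("ACDEFGHIKL"), NO_MODEL)
        cands = scan_proteome(variants, proteome, max_mismatch=0,
                              max_start_offset=0, met_start=True)
        assert len(cands) == 1 and cands[0].start_offset == 1

    def test_variant_longer_than_protein_skipped(self):
        proteome = [ProteomeEntry("p1", "org", "ACD")]
        variants = enumerate_variants(parse_read("ACDEFG"), NO_MODEL)
        assert scan_proteome(variants, proteome, max_mismatch=3,
                             max_start_offset=0, met_start=False) == []

    def test_x_in_database_never_matches(self):
        proteome = [ProteomeEntry("p1", "org", "AXDEFGHIKL")]
        variants = enumerate_variants(parse_read("AXDEFGHIKL".replace("X", "C")), NO_MODEL)
        cands = scan_proteome(variants, proteome, max_mismatch=1,
                              max_start_offset=0, met_start=False)
        assert cands and cands[0].mismatches == 1

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError):
            scan_proteome([], [], max_mismatch=0)

    def test_matches_brute_force_oracle(self):
        rng = random.Random(23)
        for _ in range(20):
            proteome = self._proteome(rng, n=rng.randint(1, 50),
                                      length=rng.randint(20, 80))
            target = proteome[rng.randrange(len(proteome))]
            read_text = target.sequence[:rng.randint(8, 15)]
            variants = enumerate_variants(parse_read(read_text), ErrorModel())
            mm = rng.randint(0, 2)
            cands = scan_proteome(variants, proteome, max_mismatch=mm,
                                  max_start_offset=1, met_start=True)
            got = sorted((c.protein_id, c.start_offset, c.mismatches,
                          c.variant_sequence) for c in cands)
            assert got == _brute_force_scan(variants, proteome, mm, 1, True)

    def test_ranking_stable_under_proteome_permutation(self):
        rng = random.Random(4)
        proteome = self._proteome(rng, n=20)
        variants = enumerate_variants(parse_read(proteome[0].sequence[:10]), ErrorModel())
        baseline = scan_proteome(variants, proteome, max_mismatch=2)
        for _ in range(5):
            shuffled = proteome[:]
            rng.shuffle(shuffled)
            assert scan_proteome(variants, shuffled, max_mismatch=2) == baseline


class TestMolecularWeight:
    def test_single_glycine(self):
        assert compute_mw("G") == pytest.approx(75.07, abs=0.01)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            compute_mw("")

    def test_non_standard_residue_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            compute_mw("AGXK")

    @given(st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=30),
           st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=30))
    @settings(max_examples=100, derandomize=True)
    def test_additivity_identity(self, a, b):
        water = compute_mw("G") - 57.0519  # recover the water term
        assert compute_mw(a + b) == pytest.approx(
            compute_mw(a) + compute_mw(b) - water, abs=1e-6)

    def test_agrees_with_independent_average_mass_oracle(self):
        pyteomics_mass = pytest.importorskip("pyteomics.mass")
        rng = random.Random(6)
        for _ in range(10):
            seq = "".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randint(5, 60)))
            oracle = pyteomics_mass.calculate_mass(sequence=seq, average=True)
            assert compute_mw(seq) == pytest.approx(oracle, rel=2e-4)


class TestMWValidation:
    def test_thirty_three_vs_thirty_passes(self):
        chk = check_mw(33.0, 30.0)
        assert chk.passed and chk.rel_dev == pytest.approx(0.10)

    def test_double_weight_fails(self):
        assert not check_mw(60.0, 30.0).passed

    def test_identity_zero_deviation(self):
        chk = check_mw(25.0, 25.0)
        assert chk.passed and chk.rel_dev == 0.0

    def test_validate_mw_populates_candidate(self):
        seq = "G" * 400  # ~22.86 kDa
        cand = MatchCandidate("p1", 0, 0)
        out = validate_mw(cand, seq, exp_kda=compute_mw(seq) / 1000.0)
        assert out.mw_check is not None and out.mw_check.passed
        assert out.mw_check.rel_dev == 0.0

    def test_tolerance_bounds_validated(self):
        with pytest.raises(ValueError):
            check_mw(30.0, 30.0, rel_tolerance=1.5)
        with pytest.raises(ValueError):
            check_mw(30.0, -1.0)


class TestMWOnlyMatch:
    def _proteome(self):
        return [
            ProteomeEntry("small", "org", "G" * 100),   # ~5.7 kDa
            ProteomeEntry("target", "org", "G" * 520),  # ~29.7 kDa
            ProteomeEntry("large", "org", "G" * 1200),  # ~68.5 kDa
        ]

    def test_unique_identification(self):
        result = mw_only_match(30.0, self._proteome())
        assert result.unique
        assert result.candidates[0].protein_id == "target"

    def test_empty_pass_set(self):
        result = mw_only_match(200.0, self._proteome())
        assert result.candidates == () and not result.unique

    def test_equals_brute_force_filter(self):
        rng = random.Random(8)
        proteome = [ProteomeEntry(f"p{i}", "org",
                                  "".join(rng.choice(AMINO_ACIDS)
                                          for _ in range(rng.randint(50, 600))))
                    for i in range(40)]
        exp = 30.0
        result = mw_only_match(exp, proteome, rel_tolerance=0.15)
        oracle = sorted(
            (abs(compute_mw(e.sequence) / 1000 - exp) / exp, e.protein_id)
            for e in proteome
            if abs(compute_mw(e.sequence) / 1000 - exp) / exp <= 0.15)
        assert [c.protein_id for c in result.candidates] == [pid for _, pid in oracle]
        assert result.unique == (len(oracle) == 1)


class TestFastaIO:
    def test_round_trip(self, tmp_path):
        entries = [ProteomeEntry("p1", "Rattus norvegicus", "MKV" * 30),
                   ProteomeEntry("p2", "Pichia stipitis", "ACDEFGHIKLMNPQRSTVWY")]
        path = tmp_path / "prot.fasta"
        assert write_proteome_fasta(entries, str(path)) == 2
        assert read_proteome_fasta(str(path)) == entries
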