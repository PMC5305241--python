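import itertools

import pytest
from hypothesis import given, settings, strategies as st

from shellcaps.core_seq import Alignment, NucSequence
from shellcaps.errors import ConfigError, SequenceError
from shellcaps.snp_effects import (
    DIAGNOSTIC, PRIVATE, UNINFORMATIVE, annotate_effect, classify_column,
    classify_variants, find_variant_columns, mutation_type,
)
from tests.conftest import DURA_CONTEXT, PISIFERA_CONTEXT


def _aln(rows: dict[str, str], labels: dict[str, str] | None = None) -> Alignment:
    return Alignment([NucSequence(k, v) for k, v in rows.items()],
                     dict(labels or {}))


class TestFindVariantColumns:
    def test_identical_sequences_no_variants(self):
        assert find_variant_columns(_aln({"a": "ACGT", "b": "ACGT"})) == []

    def test_single_sequence_errors(self):
        with pytest.raises(SequenceError):
            find_variant_columns(_aln({"a": "ACGT"}))

    def test_gap_only_difference_ignored(self):
        aln = _aln({"a": "AAAA", "b": "AA-A", "c": "AAAA", "d": "AAAA"})
        assert find_variant_columns(aln) == []

    def test_reports_planted_columns_with_both_coordinates(self):
        aln = _aln({"a": "AC-GTA", "b": "ACCGTA", "c": "ACCGAA"})
        cols = find_variant_columns(aln)
        assert [c.column for c in cols] == [5]
        assert cols[0].degapped_pos == {"a": 4, "b": 5, "c": 5}

    def test_synthetic_panel_recovers_planted_columns(self, cfg, panel):
        cols = find_variant_columns(panel)
        assert [c.column for c in cols] == [cfg.private_pos, cfg.diagnostic_pos]


class TestClassify:
    LABELS = {"d1": "dura", "d2": "dura", "d3": "dura",
              "p1": "pisifera", "p2": "pisifera",
              "t1": "tenera", "t2": "tenera"}

    def _one_col(self, alleles):
        rows = {k: v for k, v in alleles.items()}
        aln = _aln(rows, self.LABELS)
        (col,) = find_variant_columns(aln)
        return classify_column(col, self.LABELS)

    def test_fixed_difference_is_diagnostic(self):
        # dura all A, pisifera all T, tenera mixed
        assert self._one_col({"d1": "A", "d2": "A", "d3": "A",
                              "p1": "T", "p2": "T",
                              "t1": "A", "t2": "T"}) == DIAGNOSTIC

    def test_single_carrier_is_private(self):
        aln = _aln({"d1": "G", "d2": "G", "d3": "A",
                    "p1": "G", "p2": "G", "t1": "G", "t2": "G"}, self.LABELS)
        cols = classify_variants(aln)
        assert cols[0].classification == PRIVATE
        assert cols[0].carrier == "d3"

    def test_shared_polymorphism_uninformative(self):
        assert self._one_col({"d1": "A", "d2": "T", "d3": "A",
                              "p1": "A", "p2": "T",
                              "t1": "A", "t2": "T"}) == UNINFORMATIVE

    def test_empty_reference_group_errors(self):
        aln = _aln({"d1": "A", "d2": "T"}, {"d1": "dura", "d2": "dura"})
        (col,) = find_variant_columns(aln)
        with pytest.raises(ConfigError):
            classify_column(col, aln.labels)

    def test_diagnostic_invariant_under_group_swap(self):
        aln = _aln({"d1": "A", "d2": "A", "p1": "T", "p2": "T"},
                   {"d1": "dura", "d2": "dura", "p1": "pisifera", "p2": "pisifera"})
        (col,) = find_variant_columns(aln)
        assert classify_column(col, aln.labels, "dura", "pisifera") == DIAGNOSTIC
        assert classify_column(col, aln.labels, "pisifera", "dura") == DIAGNOSTIC


def oracle_classify(alleles: dict[str, str], labels: dict[str, str],
                    group_a: str, group_b: str) -> str:
    """Definition-by-enumeration oracle over all sequence pairs."""
    ids = list(alleles)
    a_ids = [i for i in ids if labels[i] == group_a and alleles[i] != "-"]
    b_ids = [i for i in ids if labels[i] == group_b and alleles[i] != "-"]
    fixed_a = all(alleles[x] == alleles[y] for x, y in itertools.combinations(a_ids, 2))
    fixed_b = all(alleles[x] == alleles[y] for x, y in itertools.combinations(b_ids, 2))
    differs = all(alleles[x] != alleles[y] for x in a_ids for y in b_ids)
    if fixed_a and fixed_b and differs:
        return DIAGNOSTIC
    non_gap = [i for i in ids if alleles[i] != "-"]
    for i in non_gap:
        rest = [alleles[j] for j in non_gap if j != i]
        if (len(set(rest)) == 1 and alleles[i] != rest[0]
                and len({alleles[j] for j in non_gap}) == 2):
            return PRIVATE
    return UNINFORMATIVE


class TestClassificationOracle:
    @given(st.data())
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_agrees_with_partition_enumeration(self, data):
        n = data.draw(st.integers(3, 8))
        bases = data.draw(st.lists(st.sampled_from("ACGT-"), min_size=n, max_size=n))
        ids = [f"s{i}" for i in range(n)]
        alleles = dict(zip(ids, bases))
        if len({b for b in bases if b != "-"}) < 2:
            return  # not a variant column
        for assignment in itertools.product(["dura", "pisifera", "tenera"], repeat=n):
            labels = dict(zip(ids, assignment))
            a_ok = any(labels[i] == "dura" and alleles[i] != "-" for i in ids)
            b_ok = any(labels[i] == "pisifera" and alleles[i] != "-" for i in ids)
            if not (a_ok and b_ok):
                continue
            aln = _aln({i: alleles[i] for i in ids}, labels)
            (col,) = find_variant_columns(aln)
            got = classify_column(col, labels)
            assert got == oracle_classify(alleles, labels, "dura", "pisifera")


class TestMutationType:
    @pytest.mark.parametrize("ref,alt,expected", [
        ("G", "A", "transition"),
        ("C", "T", "transition"),
        ("A", "T", "transversion"),  # standard definition
        ("G", "C", "transversion"),
        ("N", "A", "NA"),
    ])
    def test_examples(self, ref, alt, expected):
        assert mutation_type(ref, alt) == expected

    def test_identical_bases_error(self):
        with pytest.raises(SequenceError):
            mutation_type("A", "A")


class TestAnnotateEffect:
    def test_lys_to_asn_at_marker_snp(self):
        # AAA -> AAT in the shell-allele codon context: Lys -> Asn
        rec = annotate_effect(DURA_CONTEXT, 15, "T", frame=1)
        assert (rec.codon_ref, rec.codon_alt) == ("AAA", "AAT")
        assert (rec.aa_ref, rec.aa_alt) == ("K", "N")
        assert not rec.synonymous

    def test_second_base_substitution(self):
        rec = annotate_effect("AGA", 2, "C", frame=1)
        assert (rec.codon_ref, rec.codon_alt) == ("AGA", "ACA")
        assert (rec.aa_ref, rec.aa_alt) == ("R", "T")

    def test_synonymous_third_base(self):
        rec = annotate_effect("GGA", 3, "G", frame=1)
        assert rec.synonymous and rec.aa_ref == "G"

    def test_trailing_partial_codon_errors(self):
        with pytest.raises(SequenceError):
            annotate_effect("GGAC", 4, "T", frame=1)

    @given(st.text(alphabet="ACGT", min_size=3, max_size=60),
           st.integers(1, 3), st.data())
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_self_substitution_always_synonymous(self, seq, frame, data):
        usable = len(seq) - (len(seq) - frame + 1) % 3
        if usable < frame + 2:
            return
        pos = data.draw(st.integers(frame, usable))
        rec = annotate_effect(seq, pos, seq[pos - 1], frame)
        assert rec.synonymous and rec.codon_ref == rec.codon_alt


class TestPanelClassification:
    def test_default_panel_classifies_both_snps(self, cfg, panel):
        cols = classify_variants(panel)
        by_class = {c.classification: c for c in cols}
        assert set(by_class) == {PRIVATE, DIAGNOSTIC}
        assert by_class[PRIVATE].column == cfg.private_pos
        assert by_class[PRIVATE].carrier == cfg.private_carrier
        assert by_class[PRIVATE].ti_tv == "transition"       # G -> A
        assert by_class[DIAGNOSTIC].column == cfg.diagnostic_pos
        assert by_class[DIAGNOSTIC].ti_tv == "transversion"  # A -> T

    def test_panel_contexts_match_marker_codons(self, panel):
        rows = {s.id: s.seq for s in panel.sequences}
        assert DURA_CONTEXT in rows["dura_02"]
        assert PISIFERA_CONTEXT in rows["pisifera_01"]
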