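import pytest
from hypothesis import given, settings, strategies as st

from shellcaps.caps_design import RestrictionEnzyme, load_enzymes
from shellcaps.digest_genotype import (
    UNRESOLVED, BandPattern, call_fruit_form, digest, diploid_band_pattern,
    screen_cohort, segregation_test,
)
from shellcaps.errors import ConfigError, SequenceError
from shellcaps.synthetic_cohort import HINDIII


class TestDigest:
    def test_single_site_cut_after_280(self):
        # place the site so the top-strand cut (site start + 1) falls after base 280
        seq = "GCT" * 93 + "AAGCTT" + "GC" * 132 + "G"
        assert seq[279:285] == "AAGCTT" and len(seq) == 550
        assert digest(seq, HINDIII) == [280, 270]

    def test_no_site_full_length(self):
        assert digest("GC" * 275, HINDIII) == [550]

    def test_type_iis_cut_downstream_of_site(self):
        enz = RestrictionEnzyme("BseMII", "CTCAG", 15, 13)  # CTCAG(10/8)
        seq = "CTCAG" + "A" * 20
        assert digest(seq, enz) == [15, 10]

    def test_type_iis_cut_off_the_end_dropped(self):
        enz = RestrictionEnzyme("BseMII", "CTCAG", 15, 13)
        assert digest("CTCAG" + "A" * 5, enz) == [10]

    @given(st.text(alphabet="ACGT", min_size=1, max_size=300))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_fragment_conservation(self, seq):
        for enz in load_enzymes():
            frags = digest(seq, enz)
            assert sum(frags) == len(seq)
            assert all(f > 0 for f in frags)


class TestBandPattern:
    def test_merge_at_agarose_tolerance(self):
        pat = diploid_band_pattern([280, 270], [550], tolerance=15)
        assert pat.bands == [550, 280]
        assert pat.members[280] == [270, 280]

    def test_no_merge_at_tight_tolerance(self):
        pat = diploid_band_pattern([280, 270], [550], tolerance=5)
        assert pat.bands == [550, 280, 270]

    def test_homozygote_single_band(self):
        assert diploid_band_pattern([550], [550]).bands == [550]

    def test_hom_pattern_equals_single_haplotype(self):
        assert (diploid_band_pattern([280, 270], [280, 270]).bands
                == diploid_band_pattern([280, 270], [280, 270], 15).bands == [280])

    def test_empty_fragment_list_errors(self):
        with pytest.raises(SequenceError):
            diploid_band_pattern([], [550])

    @given(st.lists(st.integers(20, 600), min_size=1, max_size=6),
           st.lists(st.integers(20, 600), min_size=1, max_size=6),
           st.integers(0, 30))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_representatives_separated_beyond_tolerance(self, fa, fb, tol):
        pat = diploid_band_pattern(fa, fb, tol)
        reps = sorted(pat.bands)
        assert all(b - a > tol for a, b in zip(reps, reps[1:]))
        assert sorted(x for m in pat.members.values() for x in m) == sorted(fa + fb)


class TestCallFruitForm:
    def test_full_length_only_is_pisifera(self, marker_model):
        pat = diploid_band_pattern([550], [550])
        assert call_fruit_form(pat, marker_model) == "pisifera"

    def test_cut_fragments_only_is_dura(self, marker_model):
        frags = marker_model.cut_fragments
        pat = diploid_band_pattern(frags, frags)
        assert call_fruit_form(pat, marker_model) == "dura"

    def test_full_plus_cut_is_tenera(self, marker_model):
        pat = diploid_band_pattern(marker_model.cut_fragments, [550])
        assert call_fruit_form(pat, marker_model) == "tenera"

    def test_unexpected_pattern_unresolved(self, marker_model):
        pat = BandPattern([300, 150, 100], {300: [300], 150: [150], 100: [100]}, 15)
        assert call_fruit_form(pat, marker_model) == UNRESOLVED

    def test_het_pattern_is_merged_union_of_homs(self, marker_model, alleles):
        cut, uncut = alleles
        fa = digest(cut.seq, marker_model.enzyme)
        fb = digest(uncut.seq, marker_model.enzyme)
        het = diploid_band_pattern(fa, fb)
        hom_union = sorted(set(diploid_band_pattern(fa, fa).bands)
                           | set(diploid_band_pattern(fb, fb).bands), reverse=True)
        assert het.bands == hom_union


class TestSegregation:
    def test_perfect_1_2_1_fit(self, marker_model):
        counts = {"dura": 15, "tenera": 30, "pisifera": 15}
        _, stat, dof, p = segregation_test(counts, marker_model, "TxT")
        assert stat == 0.0 and dof == 2 and p == 1.0

    def test_hand_computed_chi_square(self, marker_model):
        # (50-25)^2/25 + (50-50)^2/50 + (0-25)^2/25 = 50
        counts = {"dura": 50, "tenera": 50, "pisifera": 0}
        _, stat, dof, _ = segregation_test(counts, marker_model, "TxT")
        assert stat == pytest.approx(50.0) and dof == 2

    def test_unknown_cross_errors(self, marker_model):
        with pytest.raises(ConfigError):
            segregation_test({"tenera": 10}, marker_model, "BC1")


class TestScreenCohort:
    def test_dxp_all_heterozygous_no_contamination(self, marker_model, alleles):
        cut, uncut = alleles
        samples = [(f"s{i}", (cut.seq, uncut.seq)) for i in range(20)]
        res = screen_cohort(samples, marker_model, "DxP")
        assert set(res.calls.values()) == {"tenera"}
        assert res.contamination == [] and res.p_value == 1.0 and res.dof == 0

    def test_dxp_contaminant_flagged(self, marker_model, alleles):
        cut, uncut = alleles
        samples = [("ok", (cut.seq, uncut.seq)), ("rogue", (cut.seq, cut.seq))]
        res = screen_cohort(samples, marker_model, "DxP")
        assert res.contamination == ["rogue"]
        assert res.p_value == 0.0

    def test_txt_counts_and_test(self, marker_model, alleles):
        cut, uncut = alleles
        samples = ([(f"d{i}", (cut.seq, cut.seq)) for i in range(15)]
                   + [(f"t{i}", (cut.seq, uncut.seq)) for i in range(30)]
                   + [(f"p{i}", (uncut.seq, uncut.seq)) for i in range(15)])
        res = screen_cohort(samples, marker_model, "TxT")
        assert res.counts == {"dura": 15, "tenera": 30, "pisifera": 15}
        assert res.chi_square == 0.0 and res.p_value == 1.0
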