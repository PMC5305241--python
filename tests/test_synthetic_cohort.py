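import dataclasses

import numpy as np
import pytest

from shellcaps.caps_design import load_enzymes, find_caps_candidates
from shellcaps.core_seq import read_fasta, read_sample_sheet
from shellcaps.digest_genotype import digest, diploid_band_pattern, call_fruit_form
from shellcaps.errors import ConfigError
from shellcaps.insilico_pcr import amplify
from shellcaps.snp_effects import classify_variants
from shellcaps.synthetic_cohort import (
    CUT, UNCUT, EGSHP, HINDIII, GeneratorConfig, build_cohort, emit_cohort,
    make_alleles, make_panel, simulate_cross, rng_stream,
)
from shellcaps.caps_design import scan_sites
from tests.conftest import DURA_CONTEXT, PISIFERA_CONTEXT


class TestMakeAlleles:
    def test_marker_contexts_planted(self, cfg, alleles):
        cut, uncut = alleles
        cs = cfg.context_start
        assert cut.seq[cs - 1:cs + 20] == DURA_CONTEXT
        assert uncut.seq[cs - 1:cs + 20] == PISIFERA_CONTEXT

    def test_alleles_differ_only_at_diagnostic_pos(self, cfg, alleles):
        cut, uncut = alleles
        diffs = [i + 1 for i, (a, b) in enumerate(zip(cut.seq, uncut.seq)) if a != b]
        assert diffs == [cfg.diagnostic_pos]
        assert cut.seq[cfg.diagnostic_pos - 1] == "A"
        assert uncut.seq[cfg.diagnostic_pos - 1] == "T"

    def test_site_counts_cut_one_uncut_zero(self, cfg, alleles):
        cut, uncut = alleles
        cut_hits = scan_sites(cut.seq, HINDIII)
        assert len(cut_hits) == 1 and not scan_sites(uncut.seq, HINDIII)
        lo = cut_hits[0].position
        assert lo <= cfg.diagnostic_pos <= lo + 5  # site spans the SNP

    def test_primer_footprints_at_ends(self, cfg, alleles):
        for allele in alleles:
            assert allele.seq.startswith(EGSHP.forward)
            from shellcaps.core_seq import reverse_complement
            assert allele.seq.endswith(reverse_complement(EGSHP.reverse))

    def test_deterministic_per_seed(self):
        a1 = make_alleles(GeneratorConfig(seed=5))
        a2 = make_alleles(GeneratorConfig(seed=5))
        b = make_alleles(GeneratorConfig(seed=6))
        assert (a1[0].seq, a1[1].seq) == (a2[0].seq, a2[1].seq)
        assert a1[0].seq != b[0].seq

    def test_infeasible_diagnostic_pos(self):
        with pytest.raises(ConfigError):
            make_alleles(GeneratorConfig(diagnostic_pos=10))

    def test_private_pos_inside_context_rejected(self):
        with pytest.raises(ConfigError):
            make_alleles(GeneratorConfig(private_pos=245))


class TestSimulateCross:
    def test_dxp_forced_heterozygosity(self):
        rng = np.random.default_rng(0)
        progeny = simulate_cross((CUT, CUT), (UNCUT, UNCUT), 500, rng)
        assert all(sorted(g) == [CUT, UNCUT] for g in progeny)

    def test_txt_fractions_within_three_se(self):
        rng = np.random.default_rng(1)
        n = 10_000
        progeny = simulate_cross((CUT, UNCUT), (CUT, UNCUT), n, rng)
        counts = {"cut_hom": 0, "het": 0, "uncut_hom": 0}
        for g in progeny:
            key = {0: "uncut_hom", 1: "het", 2: "cut_hom"}[g.count(CUT)]
            counts[key] += 1
        for key, p in [("cut_hom", 0.25), ("het", 0.5), ("uncut_hom", 0.25)]:
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts[key] / n - p) < 3 * se

    def test_seeded_reproducibility(self):
        g1 = simulate_cross((CUT, UNCUT), (CUT, UNCUT), 50, np.random.default_rng(9))
        g2 = simulate_cross((CUT, UNCUT), (CUT, UNCUT), 50, np.random.default_rng(9))
        assert g1 == g2

    def test_nonpositive_n_errors(self):
        with pytest.raises(ConfigError):
            simulate_cross((CUT, CUT), (CUT, CUT), 0, np.random.default_rng(0))


class TestPanel:
    def test_planted_variants_recovered_across_seeds(self):
        for seed in range(12):
            cfg = GeneratorConfig(seed=seed)
            cols = classify_variants(make_panel(cfg))
            got = {c.classification: c.column for c in cols}
            assert got == {"private": cfg.private_pos,
                           "diagnostic": cfg.diagnostic_pos}, f"seed {seed}"

    def test_hindiii_always_a_candidate_across_seeds(self):
        enzymes = load_enzymes()
        for seed in range(12):
            cut, uncut = make_alleles(GeneratorConfig(seed=seed))
            names = {c.enzyme.name for c in find_caps_candidates(cut, uncut, enzymes)}
            assert "HindIII" in names, f"seed {seed}"


class TestCohort:
    def test_design_sizes(self, cfg):
        individuals, haplotypes = build_cohort(cfg, [("DxP", 80), ("TxT", 60)])
        assert len(individuals) == 140
        assert len(haplotypes) == 280
        assert all(ind.true_form == "tenera" for ind in individuals
                   if ind.cross == "DxP")

    def test_emit_and_round_trip_recalling(self, cfg, marker_model, tmp_path):
        paths = emit_cohort(cfg, [("DxP", 10), ("TxT", 12)], tmp_path)
        haps = {r.id: r.seq for r in read_fasta(paths["haplotypes"])}
        truth = {}
        for line in open(paths["truth"]).read().strip().splitlines()[1:]:
            sid, form, a1, a2 = line.split("\t")
            truth[sid] = form
        sheet_lines = open(paths["samples"]).read().strip().splitlines()[1:]
        assert len(sheet_lines) == 22 and len(haps) == 44
        for line in sheet_lines:
            sid, h1, h2, cross = line.split("\t")
            pat = diploid_band_pattern(digest(haps[h1], marker_model.enzyme),
                                       digest(haps[h2], marker_model.enzyme))
            assert call_fruit_form(pat, marker_model) == truth[sid]

    def test_templates_amplify_to_haplotypes(self, cfg, tmp_path):
        paths = emit_cohort(cfg, [("TxT", 4)], tmp_path)
        haps = {r.id: r.seq for r in read_fasta(paths["haplotypes"])}
        for t in read_fasta(paths["templates"]):
            prods = amplify(t, cfg.primer_pair)
            assert len(prods) == 1
            assert prods[0].seq == haps[t.id.removesuffix("_template")]

    def test_error_rate_reproducible_and_primer_safe(self, tmp_path):
        cfg = GeneratorConfig(seed=2, error_rate=0.01)
        _, haps1 = build_cohort(cfg, [("DxP", 5)])
        _, haps2 = build_cohort(cfg, [("DxP", 5)])
        assert haps1 == haps2
        from shellcaps.core_seq import reverse_complement
        for seq in haps1.values():
            assert seq.startswith(EGSHP.forward)
            assert seq.endswith(reverse_complement(EGSHP.reverse))

    def test_unknown_cross_rejected(self, cfg):
        with pytest.raises(ConfigError):
            build_cohort(cfg, [("BC1", 5)])

    def test_empty_design_valid_outputs(self, cfg, tmp_path):
        paths = emit_cohort(cfg, [], tmp_path)
        assert open(paths["samples"]).readline().startswith("sample_id")
        with pytest.raises(Exception):
            read_sample_sheet(paths["samples"])  # no rows: explicit empty error
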