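# Methods

## The marker model

The assay modelled throughout is a codominant single-enzyme CAPS marker on a
linear PCR product. A primer pair (default EgSHP,
forward `TTGCTTTTAATTTTGCTTGAATACC`, reverse `TTTGGATCAGGGATAAAAGGGAAG`)
amplifies a 550 bp region of the shell gene. One allele ("cut", carried by
dura palms) contains a single HindIII recognition site `AAGCTT` spanning the
diagnostic SNP; the other ("uncut", pisifera) does not. Complete digestion of
the diploid PCR product then produces two fragments for cut homozygotes, the
full-length product for uncut homozygotes, and the three-band superposition
for heterozygotes (tenera). All calling logic operates on band *structure*
(full-length present / cut-fragment set present), never on gel-read sizes:
gel estimates of fragment lengths are not additive (estimates of 280 + 250
for a 550 bp product are typical), so exact in-silico lengths are used
internally and band counts are the reported observable.

Coordinates are 1-based and inclusive on the forward strand everywhere
user-facing. Because a published SNP position may index either the alignment
column or the degapped amplicon, both readouts are always emitted; on the
gap-free synthetic panel they coincide.

## Synthetic cohort generator

The generator defines the study conditions; it emulates the structure of the
sequenced shell-allele amplicons rather than their actual flanking sequence
(which is unknown here):

- amplicon length 550 bp; primer footprints at the ends;
- diagnostic SNP at position 248, alleles A (cut) / T (uncut), embedded in
  the codon context `GGACTGCTGAAGAA[A/T]GCTTAT` so that the A allele carries
  exactly one HindIII site spanning the SNP;
- private SNP at position 169 (major G, minor A in a single dura individual,
  `dura_01` by default) — present by default so the diagnostic/private
  distinction is always exercised;
- flanks of 200 bp each side of the amplicon on genomic templates, with
  three SSR motifs — (T)10, (CTT)4, (AAAG)3 — planted in the left flank.
  Guard bases adjacent to each planted repeat prevent random neighbours from
  extending it, so the planted unit count is exact by construction;
- background sequence is uniform-random A/C/G/T, then scrubbed by local
  rewriting until neither allele contains a spurious HindIII site or
  spurious primer footprint, and templates yield exactly one PCR product.
  This *guarantees* the single-site assumption of the assay — a modelling
  choice, not a property of real flanking DNA;
- per-base substitution error (default 0) never touches primer footprints:
  assay robustness to primer-site mutations is not the simulated question;
- cross designs: D×P (cut/cut × uncut/uncut, forced heterozygosity) and
  T×T (heterozygote selfing-type cross, 1:2:1). Default cohort sizes are
  80 D×P and 60 T×T progenies, matching the validation screen modelled.
- the sequencing panel holds one row per sequenced allele: 3 dura, 3
  pisifera and 6 tenera haplotypes (tenera alleles were sequenced
  separately, so heterozygotes appear as two haplotype rows, never as IUPAC
  heterozygote codes).

All randomness flows from a single seed through named substreams
(`rng_stream(seed, name)`), so adding a consumer never perturbs another
stage's draws, and a run is byte-reproducible from its resolved config.

What passing tests on these cohorts shows: the detection, classification,
digestion, calling and segregation machinery is correct on data with the
assumed structure. What it does not show: robustness to real-world
complications the generator deliberately omits — partial digestion, PCR
failure, trace-quality miscalls inside primer sites, compound/interrupted
SSRs, structural variation between alleles, or gel-scoring error beyond the
band-merge tolerance.

## Key parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| SSR minimum units (mono…hexa) | 10, 6, 4, 3, 3, 3 | repeats | the EST-SSR search criteria used for the shell-region markers |
| `max_mismatch` (PCR) | 0, exact 3' base | mismatches | the assay is a single robust product; terminal mismatches kill extension |
| amplicon size window | 100–2000 | bp | plausible single-product PCR range |
| CAPS window | 30 | bp | a differing site must lie within this distance of a differing base |
| `min_fragment` / `min_separation` | 80 / 30 | bp | agarose practicality: fragments visible, distinguishing bands separable |
| band-merge tolerance | 15 | bp | emulates agarose resolution; a CLI knob because real gels vary |
| segregation test | chi-square GoF | — | 1:2:1 for T×T (dof 2); D×P expects a single class (dof 0), so any non-heterozygote is reported as contamination rather than entering a degenerate test |
| GLM thresholds | 0.01, 0.001 | P | raw thresholds, no multiple-testing correction; the expected false-flag count (#tests × threshold) is reported instead |

The default cut position places the two cut fragments ≈56 bp apart, beyond
the 15 bp merge tolerance, so the cut-homozygote pattern resolves as two
bands. Whether the real fragments are gel-separable cannot be derived from
published gel estimates; this is a generator choice, documented as such.

## Variant classification

A column is **diagnostic** iff the two reference groups (default dura and
pisifera) are each fixed and for different bases — 100% within-group
agreement, no frequency threshold, because the marker claim for a codominant
diagnostic is absolute and the private/diagnostic distinction is precisely
the point. Sequences outside the reference groups (tenera) are reported but
ignored by the fixation test. A column is **private** iff exactly one
sequence in the whole panel carries a minor allele; anything else is
uninformative. Gaps are never alleles. Diagnostic takes precedence over
private when both definitions are met (e.g. a reference group of size one).

Mutation types use the standard definition (purine↔purine /
pyrimidine↔pyrimidine = transition). Note that an A↔T substitution is a
transversion; source descriptions of shell-allele SNPs have labelled it
otherwise, and this package keeps the standard definition.

Codon effects substitute the alternate base into the codon grid of a stated
reading frame and translate both codons; frame is part of the marker model
(`GeneratorConfig.effect_frame` aligns the grid with the planted codon
context). Codons containing any ambiguity code translate to `X` rather than
erroring, since deposited traces may contain N.

## SSR mining conventions

Perfect tandem repeats of period 1–6, complete units only, maximal (not
extendable by a full motif copy, and no longer same-period hit covers the
run), motifs reported primitive (shortest period: `ATATAT` is (AT)3, never
(ATAT)…), `N` breaks a run, overlapping hits of different periods are all
reported, and no compound/interrupted-repeat merging is attempted (how such
repeats were counted in the original screens is not defined, so no guess is
made). The implementation is chain-based; tests verify exact equivalence
with an enumerate-every-(start, period, count) oracle.

## Restriction digestion

Recognition sites are IUPAC-degenerate and scanned on both strands
(palindromic sites once). A plus-strand site starting at p cuts the top
strand after base p−1+`cut_top`; a minus-strand site after base
p+len(site)−1−`cut_bottom`. Type-IIS enzymes (offsets beyond the site) are
supported; cuts falling outside the molecule are dropped. Digestion is
complete and linear (the substrate is a PCR product); partial digestion is
not modelled. The shipped enzyme table carries HindIII (`A^AGCTT`) plus
BseMII `CTCAG(10/8)`, MboII `GAAGA(8/7)`, EcoP15I `CAGCAG(25/27)` and NaeI
`GCC^GGC` in REBASE-style offsets.

## Association GLM

Ordinary least squares of a trait on [intercept | Q covariates | marker],
marker coded as a categorical factor (k−1 indicators) because a codominant
fruit-form marker is a 3-class factor and dosage coding would impose an
ordering. Significance is the partial F test against the covariates-only
model; the marker's explained variance is the incremental
R² = (RSS_reduced − RSS_full)/TSS. Aliased marker columns are dropped
(incremental rank check); monomorphic markers are skipped with a reason, not
an exception. Missing data are excluded pairwise. The kinship-based mixed
model is out of scope.

Calibration is by simulation. Type-I error is measured on fully null draws
(1,000 replicates, n = 100, three-class 1:2:1 marker) and sits near the
nominal 0.05. The power check asks whether a marker *explaining 12% of a
trait's variance* — the quantity association tables report next to each P
value, i.e. the realized incremental R² — is flagged at P < 0.001 with
n = 100. Association tables that pair R² ≈ 12.9% with P ≈ 1e-4 at n = 100
behave as single-df contrasts (a 2-df contrast with that R² would give
P ≈ 1.2e-3), so the power simulation uses a biallelic marker and composes
each replicate's trait from the marker contrast and an orthogonalised noise
component such that the marker explains exactly 12% of the variance. Under
this design the flag is essentially certain (F ≈ 13.4 on 1 and 98 df,
P ≈ 4e-4). For a *population* effect of 12% the noncentral-F power at 0.001
is materially lower (≈0.62 for 1 df, ≈0.49 for 2 df) — visible in the demo
scan, where the causal 3-class marker lands near P ≈ 1e-3; detecting such
effects reliably at 0.001 requires larger n or a stronger effect.

## Numerical and degenerate-input choices

- Band merging is single-linkage on sorted lengths; representatives are the
  longest member, so representatives of distinct bands always differ by more
  than the tolerance. Ties and chaining are therefore deterministic.
- `call_fruit_form` returns the string `unresolved` for any band structure
  outside the model (a value, not an error), so cohort screening never
  aborts on one bad sample; unresolved calls are excluded from the
  segregation expectation and, in D×P cohorts, flagged as contamination.
- CAPS candidate ranking breaks ties by fewer total fragments, then enzyme
  name; the resolvability criterion compares the smallest fragment unique to
  each allele.
- Ragged alignments, empty FASTA files, unknown crosses, zero-member
  reference groups and infeasible generator configurations all raise typed
  errors naming the offending quantity; config validation reports every
  violation at once.

## Known limitations

- The generator's flanks are random; coordinates of the real amplicon on its
  source scaffold are not modelled, and the accession-based alignment of the
  deposited shell alleles is only reproducible where those sequences are
  available to the user (the same detector then applies unchanged to any
  labelled alignment).
- dCAPS (mismatch-primer) design, melting-temperature modelling, partial
  digestion, star activity and methylation sensitivity are out of scope.
- Expected product sizes of the legacy EST-SSR primer panel depend on their
  genomic source sequence and are not reproduced.
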