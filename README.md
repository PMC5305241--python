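# shellcaps

CAPS marker design and in-silico screening for oil palm fruit-form genotyping.

## The problem

Oil palm (*Elaeis guineensis*) fruit form is controlled by the shell-thickness
locus *Sh* (the SHELL MADS-box gene): thick-shelled **dura** palms are *Sh/Sh*,
shell-less **pisifera** are *sh/sh*, and the commercially valuable thin-shelled
**tenera** is the *Sh/sh* heterozygote from a dura × pisifera (D×P) cross.
Fruit form only becomes visible 4–5 years after planting, so breeders want a
codominant DNA marker that classifies seedlings.

A CAPS (cleaved amplified polymorphic sequence) marker provides exactly that:
a ~550 bp product amplified from the shell gene with the EgSHP primer pair
carries a diagnostic SNP — `A` in the dura allele, `T` in the pisifera allele —
and the `A` allele creates a single HindIII site (`AAGCTT`) spanning the SNP.
Digesting the amplicon therefore yields

| fruit form | genotype | gel-resolvable bands |
|-----------|----------|----------------------|
| dura      | cut/cut  | 2 (the two cut fragments) |
| tenera    | cut/uncut | 3 (full length + both cut fragments) |
| pisifera  | uncut/uncut | 1 (full-length product) |

At the protein level the SNP changes the fifth codon of the marker context
`GGA CTG CTG AAG AA[A/T] GCT TAT` from `AAA` (Lys) to `AAT` (Asn):
`GLLKKAY` → `GLLKNAY`.

The package implements every computational stage of developing and using such
a marker: SSR motif mining with class-specific repeat thresholds, in-silico
PCR, diagnostic/private SNP classification in group-labelled alignments,
codon-effect annotation, differential restriction-site (CAPS) discovery,
in-silico digestion with agarose-resolution band merging, fruit-form calling,
Mendelian segregation QC (D×P all-heterozygous; T×T 1:2:1 chi-square), and a
single-marker GLM association scan with structure covariates. A seeded
synthetic-cohort generator reproduces the statistical structure of the real
amplicons so every stage runs and is testable without downloads.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort (defaults: seed 1, 80 D×P + 60 T×T progenies, error rate 0):

```bash
python analysis/01_simulate_cohort.py     # emit haplotypes/templates/truth
python analysis/02_insilico_pcr.py        # EgSHP amplification
python analysis/03_variant_discovery.py   # SNP discovery + classification
python analysis/04_caps_screen.py         # enzyme screen + fragment prediction
python analysis/05_cohort_validation.py   # genotyping + segregation tests
python analysis/06_association_scan.py    # GLM marker-trait scan
```

which prints (abridged):

```
simulated 140 palms ([('DxP', 80), ('TxT', 60)]) -> results/cohort
amplified 280/280 templates (0 ambiguous); product lengths: {550: 280}
2 variant column(s) in a 12-haplotype panel
  column 169: private (transition, carrier dura_01)
  column 248: diagnostic (transversion)
  diagnostic SNP effect: codon AAA->AAT, amino acid K->N (non-synonymous)
screened 5 enzymes; 1 CAPS candidate(s)
  HindIII: site destroyed near SNP at [248]; cut-allele fragments [247, 303], uncut [550]
DxP: n=80 counts[tenera:80] chi2=0.000 (dof 0) p=1 contamination=0
TxT: n=60 counts[dura:12,pisifera:15,tenera:33] chi2=0.900 (dof 2) p=0.638 contamination=0
calls correct: 140/140 (100.0%)
```

Reading: the variant detector recovers both planted SNPs — the private one
(a single dura carrier, G→A transition at 169) and the group-diagnostic one
(A/T at 248) — HindIII is the only enzyme of the five screened whose site set
distinguishes the alleles near the SNP, every D×P progeny types as tenera,
and the T×T progeny counts are consistent with 1:2:1 Mendelian segregation.

The same functionality is exposed as a CLI (`shellcaps --help`) with
subcommands `mine-ssrs`, `pcr`, `discover-snps`, `design-caps`, `digest`,
`genotype`, `simulate`, `associate` and `run` (full pipeline from a YAML
config, with a checksummed artifact manifest and byte-reproducible outputs).

## Layout

- `src/shellcaps/` — the library (sequence primitives, SSR mining, in-silico
  PCR, SNP effects, CAPS design, digestion/genotyping, synthetic cohorts,
  association GLM, pipeline + CLI)
- `analysis/` — numbered narrative drivers over the library
- `tests/` — pytest suite with brute-force oracles and property tests
- `docs/methods.md` — model, assumptions, parameter choices, limitations
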