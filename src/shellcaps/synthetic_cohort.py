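"""Synthetic shell-locus cohorts: alleles, templates, diploid individuals, crosses.

The generator emulates the structure of the sequenced 550 bp shell-gene
amplicons: a product delimited by the EgSHP primer pair carrying one
group-diagnostic SNP (A in the cut/dura allele, T in the uncut/pisifera
allele; the A allele creates a single HindIII site spanning the SNP) and one
private SNP (G, with A in a single dura individual).  Background sequence is
uniform-random and then scrubbed so that no spurious HindIII site and no
spurious primer footprint exists — the single-site assumption the CAPS assay
relies on holds by construction, which is a modelling choice, not a property
of real flanking sequence.

All randomness flows from ``GeneratorConfig.seed`` through named substreams,
so adding one consumer never perturbs another's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .caps_design import RestrictionEnzyme, scan_sites
from .core_seq import Alignment, NucSequence, reverse_complement
from .errors import ConfigError
from .insilico_pcr import PrimerPair, find_binding_sites
from .digest_genotype import MarkerModel

EGSHP = PrimerPair(
    name="EgSHP",
    forward="TTGCTTTTAATTTTGCTTGAATACC",
    reverse="TTTGGATCAGGGATAAAAGGGAAG",
)

HINDIII = RestrictionEnzyme("HindIII", "AAGCTT", 1, 5)

#: diagnostic-SNP codon context; {} takes the allele base (offset 15, 1-based)
_CONTEXT_TEMPLATE = "GGACTGCTGAAGAA{}GCTTAT"
_CONTEXT_SNP_OFFSET = 15  # 1-based position of the SNP within the 21-mer

CUT, UNCUT = "cut", "uncut"

FORM_BY_GENOTYPE = {
    (CUT, CUT): "dura",
    (UNCUT, UNCUT): "pisifera",
    (CUT, UNCUT): "tenera",
}

#: cross id -> (parent1 genotype, parent2 genotype)
CROSS_PARENTS = {
    "DxP": ((CUT, CUT), (UNCUT, UNCUT)),
    "TxT": ((CUT, UNCUT), (CUT, UNCUT)),
}


def fruit_form(genotype: tuple[str, str]) -> str:
    return FORM_BY_GENOTYPE[tuple(sorted(genotype))]


def rng_stream(seed: int, name: str) -> np.random.Generator:
    """A named, reproducible substream of the top-level seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic locus (units: bp, 1-based)."""

    amplicon_length: int = 550
    diagnostic_pos: int = 248
    diagnostic_alleles: tuple[str, str] = ("A", "T")   # (cut base, uncut base)
    private_pos: int = 169
    private_alleles: tuple[str, str] = ("G", "A")      # (major, minor)
    private_carrier: str = "dura_01"
    flank_length: int = 200
    error_rate: float = 0.0
    seed: int = 0
    flank_ssrs: tuple[tuple[str, int], ...] = (("T", 10), ("CTT", 4), ("AAAG", 3))
    primer_pair: PrimerPair = field(default=EGSHP)
    enzyme: RestrictionEnzyme = field(default=HINDIII)

    @property
    def context_start(self) -> int:
        """1-based amplicon position of the 21-mer codon context."""
        return self.diagnostic_pos - _CONTEXT_SNP_OFFSET + 1

    @property
    def context_span(self) -> tuple[int, int]:
        cs = self.context_start
        return cs, cs + len(_CONTEXT_TEMPLATE.format("A")) - 1

    @property
    def planted_site_start(self) -> int:
        """1-based start of the HindIII site the cut allele carries."""
        return self.diagnostic_pos - 1

    @property
    def effect_frame(self) -> int:
        """Reading frame (1|2|3) on the amplicon aligning codons with the context."""
        return (self.context_start - 1) % 3 + 1

    def validate(self) -> None:
        lf, lr = len(self.primer_pair.forward), len(self.primer_pair.reverse)
        lo, hi = self.context_span
        if lo <= lf:
            raise ConfigError(
                f"diagnostic_pos {self.diagnostic_pos} infeasible: codon context "
                f"(starting at {lo}) would overlap the forward primer (1..{lf})"
            )
        if hi > self.amplicon_length - lr:
            raise ConfigError("codon context would overlap the reverse primer")
        if not lf < self.private_pos <= self.amplicon_length - lr:
            raise ConfigError("private_pos must lie between the primer footprints")
        if lo <= self.private_pos <= hi:
            raise ConfigError("private_pos overlaps the diagnostic codon context")
        if not 0.0 <= self.error_rate < 1.0:
            raise ConfigError("error_rate must be in [0, 1)")
        if self.flank_length < 0:
            raise ConfigError("flank_length must be >= 0")


def _random_bases(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(list("ACGT"), size=n)) if n else []


def _mutate(chars: list[str], j: int, rng: np.random.Generator) -> None:
    alternatives = [b for b in "ACGT" if b != chars[j]]
    chars[j] = alternatives[rng.integers(len(alternatives))]


def _primer_violations(seq: str, cfg: GeneratorConfig,
                       expect_fwd: int, expect_rev: int) -> list[tuple[int, int]]:
    """0-based windows of unexpected primer footprints on ``seq``."""
    pair = cfg.primer_pair
    bad = []
    for s in find_binding_sites(seq, pair.forward):
        if not (s.strand == "+" and s.position == expect_fwd):
            bad.append((s.position - 1, s.position - 1 + len(pair.forward)))
    for s in find_binding_sites(seq, pair.reverse):
        if not (s.strand == "-" and s.position == expect_rev):
            bad.append((s.position - 1, s.position - 1 + len(pair.reverse)))
    return bad


def make_alleles(cfg: GeneratorConfig,
                 rng: np.random.Generator | None = None) -> tuple[NucSequence, NucSequence]:
    """Build the cut (dura-type) and uncut (pisifera-type) amplicon alleles.

    The two sequences share their random background, differ exactly at
    ``diagnostic_pos``, carry the primer footprints at the amplicon ends and
    the private-SNP major base at ``private_pos``; the cut allele carries
    exactly one enzyme site (spanning the SNP), the uncut allele none.
    """
    cfg.validate()
    rng = rng if rng is not None else rng_stream(cfg.seed, "alleles")
    L = cfg.amplicon_length
    pair, enzyme = cfg.primer_pair, cfg.enzyme
    lf, lr = len(pair.forward), len(pair.reverse)

    cut_base, uncut_base = (b.upper() for b in cfg.diagnostic_alleles)
    cut_ctx = _CONTEXT_TEMPLATE.format(cut_base)
    uncut_ctx = _CONTEXT_TEMPLATE.format(uncut_base)
    if len(scan_sites(cut_ctx, enzyme)) != 1 or scan_sites(uncut_ctx, enzyme):
        raise ConfigError(
            "diagnostic_alleles must create the enzyme site on the cut allele only"
        )

    bg = _random_bases(rng, L)
    bg[:lf] = list(pair.forward)
    bg[L - lr:] = list(reverse_complement(pair.reverse))
    bg[cfg.private_pos - 1] = cfg.private_alleles[0].upper()
    cs0 = cfg.context_start - 1
    protected = set(range(lf)) | set(range(L - lr, L))
    protected |= set(range(cs0, cs0 + len(cut_ctx)))
    protected.add(cfg.private_pos - 1)

    def build() -> tuple[list[str], list[str]]:
        cut = list(bg)
        cut[cs0:cs0 + len(cut_ctx)] = list(cut_ctx)
        uncut = list(bg)
        uncut[cs0:cs0 + len(uncut_ctx)] = list(uncut_ctx)
        return cut, uncut

    for _ in range(200):
        cut, uncut = build()
        windows: list[tuple[int, int]] = []
        for chars in (cut, uncut):
            s = "".join(chars)
            for hit in scan_sites(s, enzyme):
                if hit.position != cfg.planted_site_start:
                    windows.append((hit.position - 1, hit.position - 1 + len(enzyme.site)))
            windows.extend(_primer_violations(s, cfg, 1, L - lr + 1))
        if not windows:
            break
        for lo, hi in windows:
            for j in range(lo, hi):
                if j not in protected:
                    _mutate(bg, j, rng)
                    break
    else:
        raise ConfigError("could not scrub spurious sites from the allele background")

    cut, uncut = build()
    return (
        NucSequence("allele_cut", "".join(cut), "cut (dura-type) amplicon allele"),
        NucSequence("allele_uncut", "".join(uncut), "uncut (pisifera-type) amplicon allele"),
    )


def apply_errors(seq: str, rate: float, rng: np.random.Generator,
                 protected: set[int] | None = None) -> str:
    """Per-base substitution errors at ``rate``; protected 0-based positions are immune."""
    if rate <= 0:
        return seq
    chars = list(seq)
    protected = protected or set()
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for j in hits:
        if int(j) not in protected:
            _mutate(chars, int(j), rng)
    return "".join(chars)


def make_template(hap_seq: str, cfg: GeneratorConfig,
                  rng: np.random.Generator) -> str:
    """Embed a haplotype amplicon in random flanks, with SSR motifs planted left.

    The finished template yields exactly one primer product — spurious primer
    footprints arising in the flanks (or across junctions) are scrubbed.
    """
    fl = cfg.flank_length
    left = _random_bases(rng, fl)
    ssr_protected: set[int] = set()
    offset = min(10, fl)
    for motif, units in cfg.flank_ssrs:
        block = motif * units
        if offset + len(block) + 5 > fl:
            break  # flank too short for further planted repeats
        left[offset:offset + len(block)] = list(block)
        # guard bases stop the random neighbours extending or phase-shifting
        # the repeat, so the planted unit count is exact by construction
        if offset > 0:
            left[offset - 1] = next(b for b in "GCAT" if b != motif[-1])
            ssr_protected.add(offset - 1)
        guard_r = offset + len(block)
        if guard_r < fl:
            left[guard_r] = next(b for b in "GCAT" if b != motif[0])
            ssr_protected.add(guard_r)
        ssr_protected |= set(range(offset, offset + len(block)))
        offset += len(block) + 7

    right = _random_bases(rng, fl)
    lr = len(cfg.primer_pair.reverse)
    for _ in range(100):
        template = "".join(left) + hap_seq + "".join(right)
        windows = _primer_violations(
            template, cfg, fl + 1, fl + len(hap_seq) - lr + 1
        )
        if not windows:
            return template
        for lo, hi in windows:
            for j in range(lo, hi):
                if j < fl and j not in ssr_protected:
                    _mutate(left, j, rng)
                    break
                if j >= fl + len(hap_seq):
                    _mutate(right, j - fl - len(hap_seq), rng)
                    break
    raise ConfigError("could not scrub spurious primer sites from template flanks")


@dataclass(frozen=True)
class Individual:
    """A diploid palm with its true genotype and haplotype sequence ids."""

    id: str
    genotype: tuple[str, str]      # over {'cut', 'uncut'}
    haplotype_ids: tuple[str, str]
    cross: str | None = None

    @property
    def true_form(self) -> str:
        return fruit_form(self.genotype)


def simulate_cross(p1: tuple[str, str], p2: tuple[str, str], n: int,
                   rng: np.random.Generator) -> list[tuple[str, str]]:
    """Draw ``n`` progeny genotypes, one allele uniformly from each parent."""
    if n < 1:
        raise ConfigError(f"progeny count must be >= 1, got {n}")
    picks = rng.integers(0, 2, size=(n, 2))
    return [(p1[i], p2[j]) for i, j in picks]


def make_panel(cfg: GeneratorConfig, n_dura: int = 3, n_pisifera: int = 3,
               n_tenera: int = 6) -> Alignment:
    """A labelled haplotype panel mirroring a sequenced allele collection.

    One haplotype row per sequenced allele: dura rows carry the cut allele
    (the configured carrier additionally holds the private minor base),
    pisifera rows the uncut allele, and tenera rows alternate between the
    two (each tenera was sequenced as a single resolved allele).  With
    ``error_rate`` 0 the rows are exact allele copies, so the alignment is
    gap-free by construction.
    """
    if n_dura < 1 or n_pisifera < 1:
        raise ConfigError("panel needs at least one dura and one pisifera row")
    cut, uncut = make_alleles(cfg)
    err_rng = rng_stream(cfg.seed, "panel-errors")
    lf = len(cfg.primer_pair.forward)
    lr = len(cfg.primer_pair.reverse)
    primer_mask = set(range(lf)) | set(range(cfg.amplicon_length - lr,
                                             cfg.amplicon_length))

    rows, labels = [], {}
    for i in range(n_dura):
        sid = f"dura_{i + 1:02d}"
        seq = cut.seq
        if sid == cfg.private_carrier:
            seq = seq[:cfg.private_pos - 1] + cfg.private_alleles[1].upper() \
                + seq[cfg.private_pos:]
        rows.append((sid, seq, "dura"))
    for i in range(n_pisifera):
        rows.append((f"pisifera_{i + 1:02d}", uncut.seq, "pisifera"))
    for i in range(n_tenera):
        seq = cut.seq if i % 2 == 0 else uncut.seq
        rows.append((f"tenera_{i + 1:02d}", seq, "tenera"))

    records = []
    for sid, seq, group in rows:
        records.append(NucSequence(
            sid, apply_errors(seq, cfg.error_rate, err_rng, primer_mask)
        ))
        labels[sid] = group
    return Alignment(records, labels)


def default_marker_model(cfg: GeneratorConfig) -> MarkerModel:
    """The CAPS marker model implied by the generator's alleles."""
    cut, uncut = make_alleles(cfg)
    return MarkerModel.from_alleles(cut, uncut, cfg.primer_pair, cfg.enzyme)


def build_cohort(cfg: GeneratorConfig,
                 design: list[tuple[str, int]]) -> tuple[list[Individual], dict[str, str]]:
    """Simulate individuals for a cross design; returns them plus haplotype seqs.

    ``design`` pairs a cross id ('DxP' or 'TxT') with a progeny count.  Each
    individual gets two haplotype amplicon sequences (errors applied outside
    primer footprints).
    """
    cfg.validate()
    cut, uncut = make_alleles(cfg)
    allele_seq = {CUT: cut.seq, UNCUT: uncut.seq}
    lf = len(cfg.primer_pair.forward)
    lr = len(cfg.primer_pair.reverse)
    primer_mask = set(range(lf)) | set(range(cfg.amplicon_length - lr,
                                             cfg.amplicon_length))
    individuals: list[Individual] = []
    haplotypes: dict[str, str] = {}
    for cross, n in design:
        if cross not in CROSS_PARENTS:
            raise ConfigError(f"unknown cross {cross!r}; expected one of {sorted(CROSS_PARENTS)}")
        p1, p2 = CROSS_PARENTS[cross]
        cross_rng = rng_stream(cfg.seed, f"cross-{cross}")
        err_rng = rng_stream(cfg.seed, f"errors-{cross}")
        for k, genotype in enumerate(simulate_cross(p1, p2, n, cross_rng), 1):
            sid = f"{cross}_{k:03d}"
            hap_ids = (f"{sid}_h1", f"{sid}_h2")
            for hid, allele in zip(hap_ids, genotype):
                haplotypes[hid] = apply_errors(
                    allele_seq[allele], cfg.error_rate, err_rng, primer_mask
                )
            individuals.append(Individual(sid, genotype, hap_ids, cross))
    return individuals, haplotypes


def emit_cohort(cfg: GeneratorConfig, design: list[tuple[str, int]],
                out_dir) -> dict[str, str]:
    """Write haplotypes.fa, templates.fa, samples.tsv and truth.tsv to ``out_dir``.

    Returns a manifest mapping artifact names to file paths.  Reading the
    emitted files back and re-calling genotypes reproduces truth.tsv exactly
    when ``error_rate`` is 0.
    """
    from pathlib import Path

    from .core_seq import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    individuals, haplotypes = build_cohort(cfg, design)

    hap_records = [NucSequence(hid, seq) for hid, seq in haplotypes.items()]
    tmpl_rng = rng_stream(cfg.seed, "templates")
    tmpl_records = [
        NucSequence(f"{hid}_template", make_template(seq, cfg, tmpl_rng))
        for hid, seq in haplotypes.items()
    ]

    paths = {
        "haplotypes": str(out / "haplotypes.fa"),
        "templates": str(out / "templates.fa"),
        "samples": str(out / "samples.tsv"),
        "truth": str(out / "truth.tsv"),
    }
    if hap_records:
        write_fasta(hap_records, paths["haplotypes"])
        write_fasta(tmpl_records, paths["templates"])
    else:  # an empty design still yields valid (header-only) outputs
        Path(paths["haplotypes"]).write_text("")
        Path(paths["templates"]).write_text("")
    with open(paths["samples"], "w") as fh:
        fh.write("sample_id\thaplotype1_id\thaplotype2_id\tcross\n")
        for ind in individuals:
            fh.write(f"{ind.id}\t{ind.haplotype_ids[0]}\t{ind.haplotype_ids[1]}"
                     f"\t{ind.cross}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("sample_id\ttrue_form\tallele1\tallele2\n")
        for ind in individuals:
            fh.write(f"{ind.id}\t{ind.true_form}\t{ind.genotype[0]}"
                     f"\t{ind.genotype[1]}\n")
    return paths
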