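"""Restriction-site scanning and CAPS candidate discovery.

A CAPS (cleaved amplified polymorphic sequence) marker exists when a SNP
creates or destroys a restriction site, so digesting the PCR product yields
allele-specific fragment patterns.  Candidate discovery therefore asks, for
each enzyme: do the two alleles' site-position sets differ, and does a
differing site lie near (within a configurable window of) a differing base?

Recognition sites are IUPAC-degenerate; non-palindromic sites are scanned on
both strands and minus-strand hits are reported in top-strand coordinates
with a strand flag.  Type-IIS enzymes cutting downstream of their site are
supported via cut offsets beyond the site length.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .core_seq import IUPAC_SETS, NucSequence, reverse_complement
from .errors import FormatError, SequenceError


@dataclass(frozen=True)
class RestrictionEnzyme:
    """An enzyme with an IUPAC recognition site and top/bottom cut offsets.

    ``cut_top`` means: the top strand is cut after that many bases counted
    from the site start (HindIII A^AGCTT has site AAGCTT, cut_top 1).
    Offsets beyond the site length mark downstream (type-IIS) cutters.
    """

    name: str
    site: str
    cut_top: int
    cut_bottom: int

    def __post_init__(self) -> None:
        if len(self.site) < 4:
            raise SequenceError(f"{self.name}: recognition site shorter than 4 nt")
        object.__setattr__(self, "site", self.site.upper())
        for ch in self.site:
            if ch not in IUPAC_SETS:
                raise SequenceError(f"{self.name}: non-IUPAC site character {ch!r}")

    @property
    def palindromic(self) -> bool:
        return reverse_complement(self.site) == self.site

    @property
    def type_iis(self) -> bool:
        return self.cut_top > len(self.site) or self.cut_bottom > len(self.site)


@dataclass(frozen=True)
class SiteHit:
    """A recognition-site match; ``position`` is the 1-based top-strand start."""

    position: int
    strand: str  # '+' or '-'


def _matches_at(seq: str, site: str, i: int) -> bool:
    """Does the degenerate ``site`` match concrete ``seq`` at 0-based ``i``?"""
    for k, code in enumerate(site):
        if seq[i + k] not in IUPAC_SETS[code]:
            return False
    return True


def scan_sites(seq: str, enzyme: RestrictionEnzyme) -> list[SiteHit]:
    """All recognition-site matches on a gap-free sequence, sorted by position.

    Palindromic sites are reported once per locus (the two strands coincide);
    non-palindromic sites are scanned on both strands.
    """
    s = seq.upper()
    if "-" in s:
        raise SequenceError("scan_sites requires a gap-free sequence")
    hits = []
    probes = [(enzyme.site, "+")]
    if not enzyme.palindromic:
        probes.append((reverse_complement(enzyme.site), "-"))
    for probe, strand in probes:
        for i in range(len(s) - len(probe) + 1):
            if _matches_at(s, probe, i):
                hits.append(SiteHit(i + 1, strand))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def load_enzymes(path: str | Path | None = None) -> list[RestrictionEnzyme]:
    """Read an enzyme table TSV (name, site, cut_top, cut_bottom).

    With no path, the packaged table is used; it carries HindIII plus the
    other four enzymes screened against the shell-allele amplicon (BseMII,
    MboII, EcoP15I, NaeI).
    """
    if path is None:
        ref = resources.files("shellcaps").joinpath("data/enzymes.tsv")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
    if not rows:
        raise FormatError("empty enzyme table")
    try:
        return [
            RestrictionEnzyme(r["name"], r["site"],
                              int(r["cut_top"]), int(r["cut_bottom"]))
            for r in rows
        ]
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"bad enzyme table row: {exc}") from exc


@dataclass
class CapsCandidate:
    """An enzyme whose site set differs between two alleles near a variant."""

    enzyme: RestrictionEnzyme
    variant_positions: list[int]      # differing bases near a differing site
    sites_a: list[SiteHit]
    sites_b: list[SiteHit]
    differential: str                 # 'created' | 'destroyed' going A -> B
    fragments_a: list[int]
    fragments_b: list[int]
    separation: int                   # |min distinguishing A - min distinguishing B|

    @property
    def min_fragment(self) -> int:
        return min(self.fragments_a + self.fragments_b)


def _near(hit: SiteHit, site_len: int, pos: int, window: int) -> bool:
    lo, hi = hit.position, hit.position + site_len - 1
    return lo - window <= pos <= hi + window


def find_caps_candidates(
    allele_a: NucSequence,
    allele_b: NucSequence,
    enzymes: list[RestrictionEnzyme],
    window: int = 30,
) -> list[CapsCandidate]:
    """Enzymes distinguishing two aligned, gap-free alleles near their differences.

    A candidate requires (i) different site-position sets on the two alleles
    and (ii) at least one differing site within ``window`` bp of a differing
    base.  Symmetric under swapping the alleles up to created<->destroyed.
    """
    from .digest_genotype import digest  # local import: digestion lives downstream

    a, b = allele_a.seq, allele_b.seq
    if len(a) != len(b):
        raise SequenceError("alleles must be aligned to equal length")
    if "-" in a or "-" in b:
        raise SequenceError("alleles must be gap-free")
    diffs = [i + 1 for i, (x, y) in enumerate(zip(a, b)) if x != y]
    if not diffs:
        raise SequenceError("alleles are identical; no CAPS candidates exist")

    out = []
    for enz in enzymes:
        sa, sb = scan_sites(a, enz), scan_sites(b, enz)
        set_a, set_b = set(sa), set(sb)
        if set_a == set_b:
            continue
        changed = set_a ^ set_b
        near_vars = sorted({
            p for hit in changed for p in diffs
            if _near(hit, len(enz.site), p, window)
        })
        if not near_vars:
            continue
        lost = {h for h in changed if h in set_a
                and any(_near(h, len(enz.site), p, window) for p in diffs)}
        differential = "destroyed" if lost else "created"
        fa, fb = digest(a, enz), digest(b, enz)
        only_a = sorted(_multiset_diff(fa, fb))
        only_b = sorted(_multiset_diff(fb, fa))
        sep = abs(min(only_a) - min(only_b)) if only_a and only_b else 0
        out.append(CapsCandidate(
            enzyme=enz, variant_positions=near_vars,
            sites_a=sa, sites_b=sb, differential=differential,
            fragments_a=fa, fragments_b=fb, separation=sep,
        ))
    out.sort(key=lambda c: c.enzyme.name)
    return out


def _multiset_diff(xs: list[int], ys: list[int]) -> list[int]:
    """Multiset difference xs - ys."""
    pool = list(ys)
    out = []
    for x in xs:
        if x in pool:
            pool.remove(x)
        else:
            out.append(x)
    return out


def rank_candidates(
    cands: list[CapsCandidate],
    min_fragment: int = 80,
    min_separation: int = 30,
) -> list[CapsCandidate]:
    """Order candidates by gel practicality.

    A candidate is gel-friendly when its smallest allele-distinguishing
    fragments differ by at least ``min_separation`` bp and no fragment is
    shorter than ``min_fragment`` bp.  Gel-friendly candidates rank above the
    rest; ties break by fewer total fragments, then enzyme name.
    """
    def gel_friendly(c: CapsCandidate) -> bool:
        return c.separation >= min_separation and c.min_fragment >= min_fragment

    return sorted(
        cands,
        key=lambda c: (not gel_friendly(c),
                       len(c.fragments_a) + len(c.fragments_b),
                       c.enzyme.name),
    )
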