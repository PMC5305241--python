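"""In-silico digestion, diploid band patterns, fruit-form calls, cohort screening.

The genotyping model is a codominant single-enzyme CAPS assay on a linear PCR
product: one allele carries the recognition site and is cleaved ("cut"
allele, the thick-shelled dura form in the shell assay), the other does not
("uncut", pisifera), and heterozygotes (tenera) show the superposition.
Band formation emulates agarose resolution: exact in-silico fragment lengths
are merged single-linkage within a tolerance (default 15 bp) and each merged
band is represented by its longest member.  All calling logic works on band
structure (full-length present / cut fragments present), never on gel-read
sizes, which are estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import stats

from .caps_design import RestrictionEnzyme, scan_sites
from .errors import ConfigError, SequenceError
from .insilico_pcr import PrimerPair

UNRESOLVED = "unresolved"

#: cross designs with Mendelian genotype-class expectations (cut-hom, het, uncut-hom)
CROSS_EXPECTATIONS: dict[str, tuple[float, float, float]] = {
    "DxP": (0.0, 1.0, 0.0),
    "TxT": (0.25, 0.5, 0.25),
}


def digest(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Fragment lengths (5'->3' order) after complete digestion of a linear sequence.

    Cut positions derive from every recognition-site hit on either strand;
    a plus-strand site starting at p cuts the top strand after base
    p-1+cut_top, a minus-strand site after base p+len(site)-1-cut_bottom.
    Cuts falling outside the molecule (type-IIS sites near an end) are
    dropped.  Fragments always sum to len(seq); no sites means one
    full-length fragment.
    """
    s = seq.upper()
    if "-" in s:
        raise SequenceError("digest requires a gap-free sequence")
    n = len(s)
    cuts = set()
    for hit in scan_sites(s, enzyme):
        if hit.strand == "+":
            c = hit.position - 1 + enzyme.cut_top
        else:
            c = hit.position + len(enzyme.site) - 1 - enzyme.cut_bottom
        if 0 < c < n:
            cuts.add(c)
    bounds = [0] + sorted(cuts) + [n]
    return [b - a for a, b in zip(bounds, bounds[1:])]


@dataclass
class BandPattern:
    """Gel-resolvable bands: merged representative lengths plus their members."""

    bands: list[int]                       # representatives, descending (gel order)
    members: dict[int, list[int]]          # representative -> exact fragment lengths
    tolerance: int

    def __contains__(self, length: int) -> bool:
        return any(abs(length - b) <= self.tolerance for b in self.bands)


def diploid_band_pattern(
    frags_a: list[int],
    frags_b: list[int],
    tolerance: int = 15,
) -> BandPattern:
    """Merge the union of two haplotypes' fragments into gel-resolvable bands.

    Single-linkage clustering: fragments chain into one band while adjacent
    lengths differ by at most ``tolerance``; the representative is the
    longest member.  Representatives of distinct bands therefore always
    differ by more than ``tolerance``.
    """
    if tolerance < 0:
        raise SequenceError("tolerance must be >= 0")
    if not frags_a or not frags_b:
        raise SequenceError("each haplotype must contribute at least one fragment")
    pool = sorted(frags_a + frags_b)
    clusters: list[list[int]] = [[pool[0]]]
    for x in pool[1:]:
        if x - clusters[-1][-1] <= tolerance:
            clusters[-1].append(x)
        else:
            clusters.append([x])
    members = {max(c): c for c in clusters}
    return BandPattern(
        bands=sorted(members, reverse=True),
        members=members,
        tolerance=tolerance,
    )


@dataclass
class MarkerModel:
    """Everything needed to call a fruit form from a band pattern."""

    primer_pair: PrimerPair
    enzyme: RestrictionEnzyme
    amplicon_length: int
    cut_fragments: list[int]               # exact digest of the cut allele
    cut_label: str = "dura"
    uncut_label: str = "pisifera"
    het_label: str = "tenera"

    def __post_init__(self) -> None:
        labels = {self.cut_label, self.uncut_label, self.het_label}
        if len(labels) != 3:
            raise ConfigError("cut/uncut/het labels must be distinct")
        if len(self.cut_fragments) < 2:
            raise ConfigError("the cut allele must digest into >=2 fragments")

    @classmethod
    def from_alleles(cls, cut_allele, uncut_allele, primer_pair, enzyme, **kw):
        """Build the model by digesting the two reference alleles."""
        if len(cut_allele.seq) != len(uncut_allele.seq):
            raise ConfigError("reference alleles must have equal length")
        cut = digest(cut_allele.seq, enzyme)
        uncut = digest(uncut_allele.seq, enzyme)
        if len(uncut) != 1:
            raise ConfigError("the uncut allele must not carry the site")
        return cls(primer_pair=primer_pair, enzyme=enzyme,
                   amplicon_length=len(uncut_allele.seq),
                   cut_fragments=cut, **kw)

    #: expected band counts per genotype class for a single differential site
    @property
    def expected_band_counts(self) -> dict[str, int]:
        n_cut = len(diploid_band_pattern(self.cut_fragments, self.cut_fragments).bands)
        return {self.cut_label: n_cut, self.uncut_label: 1, self.het_label: n_cut + 1}


def call_fruit_form(pattern: BandPattern, model: MarkerModel) -> str:
    """Map a band pattern to a fruit-form call (or ``unresolved``).

    Full-length band only -> uncut homozygote; all cut-allele bands and no
    full-length band -> cut homozygote; full-length plus all cut bands ->
    heterozygote; any other structure -> unresolved.
    """
    tol = pattern.tolerance
    cut_reps = diploid_band_pattern(model.cut_fragments, model.cut_fragments,
                                    tolerance=tol).bands
    has_full = any(abs(b - model.amplicon_length) <= tol for b in pattern.bands)
    expected = ([model.amplicon_length] if has_full else []) + cut_reps
    cut_present = all(any(abs(b - r) <= tol for b in pattern.bands) for r in cut_reps)
    extraneous = [b for b in pattern.bands
                  if not any(abs(b - e) <= tol for e in expected)]
    if extraneous:
        return UNRESOLVED
    if has_full and cut_present:
        return model.het_label
    if has_full and len(pattern.bands) == 1:
        return model.uncut_label
    if not has_full and cut_present:
        return model.cut_label
    return UNRESOLVED


@dataclass
class CohortResult:
    """Per-sample calls plus a Mendelian goodness-of-fit for the cross design."""

    calls: dict[str, str]
    cross: str | None
    counts: dict[str, int]
    expected_ratio: tuple[float, ...] | None
    chi_square: float | None
    dof: int | None
    p_value: float | None
    contamination: list[str] = field(default_factory=list)


def segregation_test(
    counts: dict[str, int],
    model: MarkerModel,
    cross: str,
) -> tuple[tuple[float, ...], float, int, float]:
    """Chi-square goodness of fit of genotype-class counts to the cross expectation.

    TxT (heterozygote x heterozygote) expects 1:2:1 cut-hom : het : uncut-hom;
    DxP (cut-hom x uncut-hom) expects every progeny heterozygous.
    """
    if cross not in CROSS_EXPECTATIONS:
        raise ConfigError(f"unknown cross {cross!r}; expected one of {sorted(CROSS_EXPECTATIONS)}")
    ratio = CROSS_EXPECTATIONS[cross]
    classes = [model.cut_label, model.het_label, model.uncut_label]
    observed = [counts.get(c, 0) for c in classes]
    n = sum(counts.values())
    if n == 0:
        raise ConfigError("empty cohort")
    if cross == "DxP":
        # single expected class: the fit is degenerate (dof 0); perfect iff all het
        off = n - counts.get(model.het_label, 0)
        return ratio, (0.0 if off == 0 else float("inf")), 0, (1.0 if off == 0 else 0.0)
    n_classed = sum(observed)  # unresolved calls cannot enter the expectation
    if n_classed == 0:
        raise ConfigError("no classifiable calls in cohort")
    expected = [p * n_classed for p in ratio]
    stat, p = stats.chisquare(observed, expected)
    return ratio, float(stat), len(classes) - 1, float(p)


def screen_cohort(
    samples: list[tuple[str, tuple[str, str]]],
    model: MarkerModel,
    cross: str | None = None,
    tolerance: int = 15,
) -> CohortResult:
    """Digest and call every sample's haplotype pair; test segregation if a cross is given.

    ``samples`` holds (sample id, (haplotype amplicon seq, haplotype amplicon
    seq)).  For a DxP cross every non-heterozygote call is additionally
    flagged as contamination.  Unresolved calls count toward the totals but
    never toward an expected class.
    """
    calls = {}
    for sid, (hap1, hap2) in samples:
        pat = diploid_band_pattern(digest(hap1, model.enzyme),
                                   digest(hap2, model.enzyme), tolerance)
        calls[sid] = call_fruit_form(pat, model)
    counts: dict[str, int] = {}
    for c in calls.values():
        counts[c] = counts.get(c, 0) + 1
    if cross is None:
        return CohortResult(calls, None, counts, None, None, None, None)
    ratio, stat, dof, p = segregation_test(counts, model, cross)
    contamination = (
        sorted(sid for sid, c in calls.items() if c != model.het_label)
        if cross == "DxP" else []
    )
    return CohortResult(calls, cross, counts, ratio, stat, dof, p, contamination)
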