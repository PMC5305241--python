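"""Variant-column discovery and classification in group-labelled alignments.

A variant column holds at least two distinct non-gap bases.  With two labelled
reference groups (by default the dura and pisifera fruit forms) a column is

* ``diagnostic`` when the two reference groups are fixed for different bases —
  a fixed difference; sequences outside the groups (e.g. tenera haplotypes,
  which carry either allele) are ignored by the fixation test but reported;
* ``private`` when exactly one sequence in the whole panel carries a minor
  allele (the classic single-carrier SNP);
* ``uninformative`` otherwise.

The fixation test demands 100% within-group agreement — the diagnostic claim
for a codominant marker is absolute, and the private/diagnostic distinction
is exactly what separates an idiosyncratic substitution from a marker.

Mutation types follow the standard definition: purine<->purine or
pyrimidine<->pyrimidine is a transition, anything else a transversion.
A<->T is therefore a transversion (see docs/methods.md for a note on a
conflicting label in the source data description).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_seq import GAP, Alignment, translate
from .errors import ConfigError, SequenceError

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

DIAGNOSTIC = "diagnostic"
PRIVATE = "private"
UNINFORMATIVE = "uninformative"


@dataclass
class VariantColumn:
    """One polymorphic alignment column with per-sequence alleles."""

    column: int                      # 1-based alignment column
    alleles: dict[str, str]          # seq id -> base ('-' possible)
    degapped_pos: dict[str, int | None] = field(default_factory=dict)
    classification: str | None = None
    ti_tv: str | None = None         # "transition" | "transversion" | "NA"
    carrier: str | None = None       # single carrier id for private columns

    @property
    def distinct_bases(self) -> set[str]:
        return {b for b in self.alleles.values() if b != GAP}


def find_variant_columns(aln: Alignment) -> list[VariantColumn]:
    """Every column of ``aln`` with >=2 distinct non-gap bases.

    Gap-only differences are ignored (a gap is not an allele).
    """
    if len(aln) < 2:
        raise SequenceError("variant discovery needs at least 2 sequences")
    out = []
    for col in range(1, aln.n_columns + 1):
        alleles = aln.column(col)
        bases = {b for b in alleles.values() if b != GAP}
        if len(bases) >= 2:
            out.append(VariantColumn(
                column=col,
                alleles=alleles,
                degapped_pos={sid: aln.degapped_position(sid, col) for sid in alleles},
            ))
    return out


def mutation_type(ref: str, alt: str) -> str:
    """'transition', 'transversion', or 'NA' for ambiguity codes."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in "ACGT" or alt not in "ACGT":
        return "NA"
    if ref == alt:
        raise SequenceError("ref and alt must differ")
    if {ref, alt} <= _PURINES or {ref, alt} <= _PYRIMIDINES:
        return "transition"
    return "transversion"


def classify_column(
    col: VariantColumn,
    labels: dict[str, str],
    group_a: str = "dura",
    group_b: str = "pisifera",
) -> str:
    """Classify one variant column as diagnostic, private, or uninformative."""
    a_bases = {col.alleles[sid] for sid, g in labels.items()
               if g == group_a and sid in col.alleles and col.alleles[sid] != GAP}
    b_bases = {col.alleles[sid] for sid, g in labels.items()
               if g == group_b and sid in col.alleles and col.alleles[sid] != GAP}
    if not a_bases or not b_bases:
        missing = group_a if not a_bases else group_b
        raise ConfigError(f"reference group {missing!r} has no members in the alignment")
    if len(a_bases) == 1 and len(b_bases) == 1 and a_bases != b_bases:
        return DIAGNOSTIC
    counts: dict[str, int] = {}
    for base in (b for b in col.alleles.values() if b != GAP):
        counts[base] = counts.get(base, 0) + 1
    if len(counts) == 2 and min(counts.values()) == 1:
        return PRIVATE
    return UNINFORMATIVE


def classify_variants(
    aln: Alignment,
    group_a: str = "dura",
    group_b: str = "pisifera",
) -> list[VariantColumn]:
    """Discover and fully annotate variant columns (classification, ti/tv, carrier)."""
    cols = find_variant_columns(aln)
    for col in cols:
        col.classification = classify_column(col, aln.labels, group_a, group_b)
        bases = sorted(col.distinct_bases)
        col.ti_tv = mutation_type(bases[0], bases[1]) if len(bases) == 2 else "NA"
        if col.classification == PRIVATE:
            counts: dict[str, int] = {}
            for b in (x for x in col.alleles.values() if x != GAP):
                counts[b] = counts.get(b, 0) + 1
            minor = min(counts, key=counts.get)
            col.carrier = next(sid for sid, b in col.alleles.items() if b == minor)
    return cols


@dataclass(frozen=True)
class EffectRecord:
    """Codon-level consequence of a single-base substitution."""

    pos: int          # 1-based substituted position in the (degapped) sequence
    frame: int
    codon_ref: str
    codon_alt: str
    aa_ref: str
    aa_alt: str

    @property
    def synonymous(self) -> bool:
        return self.aa_ref == self.aa_alt


def annotate_effect(seq: str, pos: int, alt: str, frame: int = 1) -> EffectRecord:
    """Substitute ``alt`` at 1-based ``pos`` and report the codon/amino-acid change.

    ``frame`` fixes the codon grid (frame f puts the first codon at positions
    f..f+2).  A position falling in the trailing partial codon, or upstream of
    the frame start, is an error.
    """
    s = seq.upper().replace(GAP, "")
    alt = alt.upper()
    if not 1 <= pos <= len(s):
        raise SequenceError(f"position {pos} outside sequence of length {len(s)}")
    if frame not in (1, 2, 3):
        raise SequenceError(f"frame must be 1, 2 or 3, got {frame}")
    if pos < frame:
        raise SequenceError(f"position {pos} precedes reading frame {frame}")
    codon_index = (pos - frame) // 3
    cs = frame + 3 * codon_index  # 1-based codon start
    if cs + 2 > len(s):
        raise SequenceError(f"position {pos} lies in a trailing partial codon")
    codon_ref = s[cs - 1:cs + 2]
    offset = pos - cs
    codon_alt = codon_ref[:offset] + alt + codon_ref[offset + 1:]
    return EffectRecord(
        pos=pos, frame=frame,
        codon_ref=codon_ref, codon_alt=codon_alt,
        aa_ref=translate(codon_ref), aa_alt=translate(codon_alt),
    )
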