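"""In-silico PCR: primer binding-site search and amplicon extraction.

Matching is IUPAC-aware in both operands: a primer base matches a template
base when their IUPAC sets intersect (so a template 'N' matches anything).
The 3'-terminal primer base must match exactly regardless of the mismatch
budget — polymerase extension tolerates internal mismatches far better than
terminal ones, and the assay modelled here is reported as a single robust
product, so the default budget is zero mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_seq import IUPAC_SETS, NucSequence, reverse_complement
from .errors import SequenceError


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse primers, both stored 5'->3'."""

    name: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise SequenceError("primers must be non-empty")
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())


@dataclass(frozen=True)
class BindingSite:
    """A primer footprint: 1-based start on the plus strand, strand, mismatch count."""

    position: int
    strand: str  # '+' or '-'
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product; ``start``/``end`` are 1-based inclusive template coords."""

    template_id: str
    start: int
    end: int
    seq: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def bases_compatible(a: str, b: str) -> bool:
    """True when IUPAC codes ``a`` and ``b`` can denote a common concrete base."""
    try:
        return bool(IUPAC_SETS[a.upper()] & IUPAC_SETS[b.upper()])
    except KeyError as exc:
        raise SequenceError(f"non-IUPAC character {exc.args[0]!r}") from exc


def _scan_oriented(template: str, probe: str, max_mismatch: int,
                   three_prime_index: int) -> list[tuple[int, int]]:
    """All (0-based start, mismatches) where ``probe`` sits on ``template``.

    ``three_prime_index`` is the probe offset that must match exactly.
    """
    hits = []
    lp, lt = len(probe), len(template)
    for i in range(lt - lp + 1):
        window = template[i:i + lp]
        if not bases_compatible(probe[three_prime_index], window[three_prime_index]):
            continue
        mism = sum(not bases_compatible(p, t) for p, t in zip(probe, window))
        if mism <= max_mismatch:
            hits.append((i, mism))
    return hits


def find_binding_sites(template: str, primer: str, max_mismatch: int = 0) -> list[BindingSite]:
    """Locate primer footprints on both strands of ``template``.

    Positions are 1-based starts of the footprint in plus-strand coordinates.
    On the plus strand the primer's 3' end is the rightmost footprint base;
    on the minus strand it is the leftmost.  A primer longer than the
    template yields an empty list.
    """
    if max_mismatch < 0:
        raise SequenceError("max_mismatch must be >= 0")
    template = template.upper()
    primer = primer.upper()
    if len(primer) > len(template):
        return []
    sites = [
        BindingSite(i + 1, "+", m)
        for i, m in _scan_oriented(template, primer, max_mismatch, len(primer) - 1)
    ]
    rc = reverse_complement(primer)
    sites += [
        BindingSite(i + 1, "-", m)
        for i, m in _scan_oriented(template, rc, max_mismatch, 0)
    ]
    sites.sort(key=lambda s: (s.position, s.strand))
    return sites


def amplify(
    template: NucSequence,
    pair: PrimerPair,
    max_mismatch: int = 0,
    min_len: int = 100,
    max_len: int = 2000,
) -> list[Amplicon]:
    """Predict PCR products of ``pair`` on ``template``.

    Every plus-strand forward footprint is paired with every downstream
    minus-strand reverse footprint; products within [min_len, max_len] are
    returned sorted by start.  No products is an empty list, not an error.
    """
    if min_len > max_len:
        raise SequenceError(f"min_len {min_len} > max_len {max_len}")
    fwd = [s for s in find_binding_sites(template.seq, pair.forward, max_mismatch)
           if s.strand == "+"]
    rev = [s for s in find_binding_sites(template.seq, pair.reverse, max_mismatch)
           if s.strand == "-"]
    lf, lr = len(pair.forward), len(pair.reverse)
    out = []
    for f in fwd:
        for r in rev:
            if r.position < f.position + lf:
                continue  # reverse footprint must lie downstream of the forward one
            start, end = f.position, r.position + lr - 1
            length = end - start + 1
            if min_len <= length <= max_len:
                out.append(Amplicon(template.id, start, end,
                                    template.seq[start - 1:end]))
    out.sort(key=lambda a: (a.start, a.end))
    return out
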