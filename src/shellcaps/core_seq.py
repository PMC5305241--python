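"""Nucleotide-sequence primitives: IUPAC semantics, translation, FASTA/CLUSTAL IO.

Coordinates are 1-based and inclusive on the forward strand in every
user-facing structure; internal 0-based half-open offsets are never exposed.
Alignment columns index the gapped alignment; "degapped" offsets index each
row with gaps removed.  Both readouts are reported side by side wherever a
position is emitted, because a position quoted for a marker may follow either
convention depending on how the source alignment was built.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import AlignIO, SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, SequenceError

#: Meaning of each IUPAC nucleotide code as a set of concrete bases.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "-": "-",
}

GAP = "-"

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"


def _validate_iupac(seq: str, allow_gap: bool = False) -> str:
    """Uppercase ``seq`` and raise :class:`SequenceError` at the first bad character."""
    up = seq.upper()
    allowed = set(IUPAC_SETS)
    if allow_gap:
        allowed.add(GAP)
    for i, ch in enumerate(up):
        if ch not in allowed:
            raise SequenceError(
                f"non-IUPAC character {ch!r} at position {i + 1}"
            )
    return up


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string.

    Ambiguity codes map to their complements (R<->Y, K<->M, B<->V, D<->H;
    S, W and N are self-complementary).  Gaps are preserved.  An involution:
    ``reverse_complement(reverse_complement(s)) == s``.
    """
    up = _validate_iupac(seq, allow_gap=True)
    return "".join(_COMPLEMENT[ch] for ch in reversed(up))


def translate(seq: str, frame: int = 1) -> str:
    """Translate ``seq`` in reading frame 1, 2 or 3 under the standard genetic code.

    The trailing partial codon is dropped; stop codons render as ``'*'``.
    Gaps are stripped before translation.  A codon containing any ambiguity
    code (including N) translates to ``'X'``.
    """
    if frame not in (1, 2, 3):
        raise SequenceError(f"frame must be 1, 2 or 3, got {frame}")
    up = _validate_iupac(seq, allow_gap=True).replace(GAP, "")
    up = up[frame - 1:]
    out = []
    for i in range(0, len(up) - len(up) % 3, 3):
        codon = up[i:i + 3]
        out.append(_CODON_TABLE.get(codon, "X"))
    return "".join(out)


@dataclass
class NucSequence:
    """A named nucleotide sequence over the IUPAC alphabet (gaps allowed)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise SequenceError(f"sequence {self.id!r} is empty")
        self.seq = _validate_iupac(self.seq, allow_gap=True)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def degapped(self) -> str:
        return self.seq.replace(GAP, "")

    def reverse_complement(self) -> "NucSequence":
        return NucSequence(self.id, reverse_complement(self.seq), self.description)


@dataclass
class Alignment:
    """Equal-length rows plus a map from sequence id to group label.

    Ids without an explicit label default to ``"unknown"``.
    """

    sequences: list[NucSequence]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            detail = ", ".join(f"{s.id}:{len(s)}" for s in self.sequences)
            raise FormatError(f"ragged alignment (row lengths {detail})")
        for s in self.sequences:
            self.labels.setdefault(s.id, "unknown")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def column(self, col: int) -> dict[str, str]:
        """Bases of 1-based alignment column ``col``, keyed by sequence id."""
        if not 1 <= col <= self.n_columns:
            raise SequenceError(f"column {col} outside alignment of width {self.n_columns}")
        return {s.id: s.seq[col - 1] for s in self.sequences}

    def degapped_position(self, seq_id: str, col: int) -> int | None:
        """1-based offset of column ``col`` within the degapped row, or None at a gap."""
        row = next(s for s in self.sequences if s.id == seq_id)
        if row.seq[col - 1] == GAP:
            return None
        return col - row.seq[:col].count(GAP)


def read_fasta(path: str | Path) -> list[NucSequence]:
    records = [
        NucSequence(r.id, str(r.seq), r.description.removeprefix(r.id).strip())
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[NucSequence], path: str | Path) -> None:
    """Write multi-record FASTA wrapped at 60 columns."""
    recs = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(recs)


def read_alignment(
    path: str | Path,
    dialect: str = "fasta",
    labels: dict[str, str] | None = None,
) -> Alignment:
    """Read an aligned FASTA or CLUSTAL file into an :class:`Alignment`.

    Ragged rows raise :class:`FormatError` listing every row length.
    """
    if dialect not in ("fasta", "clustal"):
        raise FormatError(f"unknown alignment dialect {dialect!r}")
    if dialect == "fasta":
        rows = read_fasta(path)
    else:
        try:
            aln = AlignIO.read(str(path), "clustal")
        except ValueError as exc:
            raise FormatError(f"cannot parse {path} as CLUSTAL: {exc}") from exc
        rows = [NucSequence(r.id, str(r.seq)) for r in aln]
    if not rows:
        raise FormatError(f"no alignment rows in {path}")
    return Alignment(rows, dict(labels or {}))


def read_sample_sheet(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (id, group/cross label) into a dict.

    A header line is tolerated (detected by the literal first field
    ``sample_id`` or ``id``).
    """
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in ("sample_id", "id", "seq_id"):
                continue
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected >=2 tab-separated fields")
            out[parts[0]] = parts[1]
    if not out:
        raise FormatError(f"no samples in {path}")
    return out
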