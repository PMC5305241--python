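"""Microsatellite (SSR) detection with class-specific minimum repeat counts.

The miner reports perfect tandem repeats of period 1-6 whose complete-unit
count meets the per-class threshold.  Defaults follow the EST-SSR search
criteria used for the SHELL-region markers: at least 10 units for
mononucleotide repeats, 6 for di-, 4 for tri-, and 3 for tetra-, penta- and
hexanucleotide repeats.

Conventions (these make the output a well-defined function of the input):

* A hit covers complete units only; a trailing partial unit is excluded.
* A hit is maximal: it cannot be extended by a full motif copy on either
  side, and no longer hit of the same period covers the same run.
* The motif is reported at its shortest period ("ATATAT" is a (AT)3 run,
  never (ATAT)...), i.e. motifs are primitive strings.
* 'N' and other ambiguity codes break a run.
* Overlapping hits of *different* periods are all reported; no compound-SSR
  merging is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import SequenceError

#: period -> minimum number of complete repeat units
DEFAULT_THRESHOLDS: dict[int, int] = {1: 10, 2: 6, 3: 4, 4: 3, 5: 3, 6: 3}


@dataclass(frozen=True)
class SsrHit:
    """A maximal perfect tandem repeat; ``start``/``end`` are 1-based inclusive."""

    motif: str
    repeat_count: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.motif) * self.repeat_count:
            raise SequenceError("SSR hit span inconsistent with motif x count")


def is_primitive(motif: str) -> bool:
    """True if ``motif`` is not a whole-number repetition of a shorter string."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def find_ssrs(
    seq: str,
    thresholds: dict[int, int] | None = None,
) -> list[SsrHit]:
    """Find all maximal SSRs in ``seq`` meeting the per-period thresholds.

    Returns hits sorted by start position (ties by period).  An empty
    sequence yields an empty list.
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    s = seq.upper()
    n = len(s)
    hits: list[SsrHit] = []
    for period, min_units in sorted(thresholds.items()):
        if min_units < 1:
            raise SequenceError(f"threshold for period {period} must be >= 1")
        i = 0
        # chain positions where s[i] == s[i+period]; a maximal chain [i0, i1]
        # means s[i0 : i1+period+1] is a perfect period-`period` run
        while i + period < n:
            if s[i] == s[i + period] and s[i] in "ACGT":
                i0 = i
                while i + period < n and s[i] == s[i + period] and s[i + period] in "ACGT":
                    i += 1
                run_len = i - i0 + period  # length of the full periodic run
                count = run_len // period
                motif = s[i0:i0 + period]
                if count >= min_units and is_primitive(motif) and set(motif) <= set("ACGT"):
                    hits.append(
                        SsrHit(motif=motif, repeat_count=count,
                               start=i0 + 1, end=i0 + count * period)
                    )
                i = i0 + run_len - period + 1
            else:
                i += 1
    hits.sort(key=lambda h: (h.start, len(h.motif)))
    return hits


def hits_to_rows(seq_id: str, hits: list[SsrHit]) -> list[dict]:
    """Flatten hits for TSV output (seq_id, motif, repeats, start, end)."""
    return [
        {"seq_id": seq_id, "motif": h.motif, "repeats": h.repeat_count,
         "start": h.start, "end": h.end}
        for h in hits
    ]
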