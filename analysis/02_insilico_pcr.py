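#!/usr/bin/env python
"""Amplify the shell-gene product from every simulated template with EgSHP.

Reads results/cohort/templates.fa, runs in-silico PCR with the EgSHP primer
pair (zero mismatches, exact 3' anchoring) and writes the amplicons.  The
assay's premise is that every palm yields exactly one product of the same
length; the script verifies and reports that.
"""

import argparse
from collections import Counter
from pathlib import Path

from shellcaps.core_seq import NucSequence, read_fasta, write_fasta
from shellcaps.insilico_pcr import amplify
from shellcaps.synthetic_cohort import EGSHP


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    templates = read_fasta(args.out_dir / "cohort" / "templates.fa")
    amplicons, lengths = [], Counter()
    multi = 0
    for t in templates:
        prods = amplify(t, EGSHP)
        if len(prods) != 1:
            multi += 1
            continue
        lengths[prods[0].length] += 1
        amplicons.append(NucSequence(t.id.removesuffix("_template"),
                                     prods[0].seq))
    write_fasta(amplicons, args.out_dir / "amplicons.fa")
    print(f"amplified {len(amplicons)}/{len(templates)} templates "
          f"({multi} ambiguous) -> {args.out_dir / 'amplicons.fa'}")
    print(f"  product lengths: {dict(lengths)}")


if __name__ == "__main__":
    main()
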