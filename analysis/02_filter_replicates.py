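#!/usr/bin/env python
"""Remove artifactual replicate reads from both genomes' shotgun data.

Applies the prefix-clustering replicate filter (identity cutoff 0.99, full
length requirement, 3-bp initial match) and writes filtered FASTA files next
to the raw reads.
"""
import argparse
from pathlib import Path

from repeatdim import seqio
from repeatdim.models import GERMLINE, SOMA


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    simdir = args.results / "sim"
    for label in (GERMLINE, SOMA):
        reads = seqio.read_fasta(simdir / f"reads_{label}.fasta")
        kept, removed = seqio.duplicate_filter(reads)
        seqio.write_fasta(kept, simdir / f"reads_{label}.filtered.fasta")
        print(f"{label}: removed {removed}/{len(reads)} reads "
              f"({100 * removed / len(reads):.2f}%) as potential replicates")


if __name__ == "__main__":
    main()
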