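#!/usr/bin/env python
"""Assign shotgun reads to the repeat library and summarise masking.

Each read gets at most one family: the best affine local alignment passing
the >= 80 % identity and >= 100 bp overlap filters.  Writes per-genome
alignment tables and masked-bp summaries.
"""
import argparse
from pathlib import Path

from repeatdim import annotate, seqio, simkit
from repeatdim.models import GERMLINE, SOMA


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--min-identity", type=float, default=0.80)
    ap.add_argument("--min-overlap", type=int, default=100)
    args = ap.parse_args()

    simdir = args.results / "sim"
    library = seqio.read_library(simdir / "library.fasta")
    for label in (GERMLINE, SOMA):
        reads = seqio.read_fasta(simdir / f"reads_{label}.filtered.fasta")
        rs = simkit.ReadSet(label, reads)
        alns = annotate.annotate_readset(rs, library, args.min_identity,
                                         args.min_overlap)
        annotate.alignments_to_frame(alns).to_csv(
            args.results / f"alignments_{label}.tsv", sep="\t", index=False)
        mask = annotate.mask_summary(alns, rs)
        mask.to_csv(args.results / f"mask_summary_{label}.tsv", sep="\t",
                    index=False)
        total = mask.loc[mask["class"] == "TOTAL", "masked_fraction"].iloc[0]
        print(f"{label}: {len(alns)}/{len(rs)} reads assigned; "
              f"{100 * total:.1f}% of base pairs masked by the library")


if __name__ == "__main__":
    main()
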