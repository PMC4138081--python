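#!/usr/bin/env python
"""Genomic context of the accepted precursors: intronic/intergenic
classes, the 79-bp contiguous-window null model with chi-square contrast,
the flank-extension profile (0/500/1000/2000 bp) and 10-kb clusters.

Consumes precursors.gff3 from --workdir (written by 02) and writes the
context tables under --outdir.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from mirforge import context as ctx
from mirforge import discovery as disc
from mirforge import formats_io as fio


def main() -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument("--workdir", type=Path, default=Path("scratch/study"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    genome = fio.read_genome_fasta(args.workdir / "genome.fa")
    genes = fio.read_gff_annotations(args.workdir / "genes.gff3", genome)
    feats = [f for f in fio.read_precursor_gff(args.workdir / "precursors.gff3")
             if f["type"] == "miRNA_primary_transcript"]
    cands = [
        disc.CandidatePrecursor(
            f["attributes"]["ID"], f["scaffold_id"], f["interval"],
            f["strand"], "", "", 0.0, {}, 1)
        for f in feats
    ]
    annotated = [ctx.classify_location(c, genes) for c in cands]
    annotated = ctx.find_clusters(annotated)

    n = len(annotated)
    n_intra = sum(1 for a in annotated if a.location_class != "intergenic")
    null = ctx.window_null(genome, genes, 79, 0)
    stat, p, _ = ctx.compare_proportions(n_intra, n, null.n_overlapping_gene,
                                         null.n_windows)
    profile = ctx.flank_extension_profile(annotated, genome, genes)
    clustered = sum(1 for a in annotated if a.cluster_id)

    args.outdir.mkdir(parents=True, exist_ok=True)
    with open(args.outdir / "03_context_classes.tsv", "w") as fh:
        fh.write("precursor_id\tlocation\thost_gene\tcluster\tdistance_bp\n")
        for a in annotated:
            fh.write(f"{a.precursor.precursor_id}\t{a.location_class}\t"
                     f"{a.host_gene_id or '-'}\t{a.cluster_id or '-'}\t"
                     f"{a.distance_to_nearest_gene}\n")
    with open(args.outdir / "03_window_null.tsv", "w") as fh:
        fh.write("flank_bp\tprecursor_intragenic_fraction\t"
                 "window_intragenic_fraction\n")
        for row in profile:
            fh.write(f"{row['flank']}\t{row['precursor_fraction']:.4f}\t"
                     f"{row['null_fraction']:.4f}\n")
    print(f"{n} precursors: {n_intra} intragenic "
          f"({100 * n_intra / n:.0f}%) vs {100 * null.fraction:.0f}% of "
          f"79-bp windows; chi-square {stat:.1f}, P = {p:.2e}")
    print(f"{clustered} precursors ({100 * clustered / n:.0f}%) fall in "
          f"{len({a.cluster_id for a in annotated if a.cluster_id})} "
          f"clusters (gap <= 10 kb)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
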