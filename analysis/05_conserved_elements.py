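#!/usr/bin/env python
"""Conserved-element ancestry classification and feature assignment.

Merges raw elements (< 5 bp apart), classifies ancestry from per-species
alignment-depth tracks (>= 75% coverage, inclusive), assigns genomic
features, and links intergenic elements (CNEs) to their nearest gene.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from notokit.conserved import assign_feature, classify_ancestry, link_cne_to_gene, merge_ces
from notokit.io import read_bed, read_depth_track, read_gff3_genes

SPECIES = ["EleMac", "CotGob", "DisMaw", "PogAlb", "HarAnt2"]
CLADE = ["DisMaw", "PogAlb", "HarAnt2"]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    raw = read_bed(args.data / "conserved_elements_raw.bed")
    tracks = {
        sp: read_depth_track(args.data / f"depth_{sp}.bedgraph", sp) for sp in SPECIES
    }
    genes = read_gff3_genes(args.data / "genes.gff3")
    truth = json.loads((args.data / "truth_ces.json").read_text())["labels"]

    merged = merge_ces(raw, max_gap=5)
    classified = classify_ancestry(merged, tracks, SPECIES, CLADE)
    featured = assign_feature(classified, genes)
    cnes = [c for c in featured if c.feature == "intergenic" and c.ancestry == "clade_specific"]
    linked = link_cne_to_gene(cnes, genes)

    pd.DataFrame(
        {
            "chrom": [c.interval.chrom for c in featured],
            "start": [c.interval.start for c in featured],
            "end": [c.interval.end for c in featured],
            "ancestry": [c.ancestry for c in featured],
            "feature": [c.feature for c in featured],
        }
    ).to_csv(args.out / "conserved_elements.tsv", sep="\t", index=False)

    counts = pd.Series([c.ancestry for c in featured]).value_counts().to_dict()
    acc = sum(c.ancestry == t for c, t in zip(classified, truth)) / len(truth)
    print(f"{len(featured)} elements classified: {counts}")
    print(f"planted ancestry recovered on {acc:.1%} of elements")
    print(
        f"{len(cnes)} clade-specific intergenic CNEs, "
        f"{sum(1 for c in linked if c.linked_genes)} linked to a nearest gene"
    )


if __name__ == "__main__":
    main()
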