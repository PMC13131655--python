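#!/usr/bin/env python
"""Generate the synthetic analysis scenario with planted truth.

Writes every input the downstream analyses consume — SV and repeat
tables, gene models, the dated species tree, branch-mutation tables,
landscape repeat tables, conserved-element intervals and per-species
depth tracks, and gene trees — plus truth JSONs, under results/data/.
"""

import argparse
import json
from pathlib import Path

from notokit.io import (
    write_bed,
    write_branch_mutations,
    write_depth_track,
    write_gff3_genes,
    write_repeat_table,
    write_sv_table,
)
from notokit.synthetic import (
    default_layout,
    simulate_branch_mutations,
    simulate_depth_tracks,
    simulate_diploid_sv_dataset,
    simulate_gene_trees,
    simulate_repeat_divergences,
)
from notokit.intervals import GenomicInterval
from notokit.io import read_dated_tree

SPECIES_TREE = "(((HarAnt:6.86,PogAlb:6.86):3.84,DisMaw:10.7):7.0,EleMac:17.7);"
DEPTH_SPECIES = ["EleMac", "CotGob", "DisMaw", "PogAlb", "HarAnt2"]
FOCAL_CLADE = ["DisMaw", "PogAlb", "HarAnt2"]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    layout = default_layout()
    ds = simulate_diploid_sv_dataset(layout, 500, 500, seed=args.seed)
    write_sv_table(out / "svs.tsv", ds.svs)
    write_sv_table(out / "read_svs.tsv", ds.read_svs)
    write_repeat_table(out / "repeats_hap1.tsv", ds.repeats_hap1)
    write_repeat_table(out / "repeats_hap2.tsv", ds.repeats_hap2)
    write_gff3_genes(out / "genes.gff3", ds.genes)
    write_bed(out / "tandem.bed", ds.features["tandem"])
    (out / "truth_diploid.json").write_text(json.dumps(ds.truth, indent=2, sort_keys=True))
    (out / "layout.json").write_text(
        json.dumps(
            {
                "chrom_lengths": dict(layout.chrom_lengths),
                "gaps": [[g.chrom, g.start, g.end] for g in layout.gaps],
            },
            indent=2,
        )
    )

    (out / "species_tree.nwk").write_text(SPECIES_TREE + "\n")
    tree = read_dated_tree(SPECIES_TREE)
    bm = simulate_branch_mutations(tree, seed=args.seed)
    write_branch_mutations(out / "branch_mutations.tsv", bm.mutations)
    write_repeat_table(out / "branch_repeats.tsv", bm.repeats)
    (out / "truth_branches.json").write_text(json.dumps(bm.truth, indent=2, sort_keys=True))

    hits, land_truth = simulate_repeat_divergences(n=5000, seed=args.seed)
    write_repeat_table(out / "landscape_repeats.tsv", hits)
    (out / "truth_landscape.json").write_text(json.dumps(land_truth, indent=2, sort_keys=True))

    import numpy as np

    rng = np.random.default_rng([args.seed, 17])
    ces = [
        GenomicInterval("chr01", i * 700, i * 700 + int(rng.integers(50, 300)))
        for i in range(500)
    ]
    labels = [["ancestral", "clade_specific", "other"][int(rng.integers(3))] for _ in ces]
    write_bed(out / "conserved_elements_raw.bed", ces)
    tracks = simulate_depth_tracks(ces, labels, DEPTH_SPECIES, FOCAL_CLADE, seed=args.seed)
    for sp, track in tracks.items():
        write_depth_track(out / f"depth_{sp}.bedgraph", track)
    (out / "truth_ces.json").write_text(json.dumps({"labels": labels}, indent=2))

    gt = simulate_gene_trees(
        200, FOCAL_CLADE, "EleMac", ["CotGob", "GasAcu", "TakRub"], seed=args.seed
    )
    tdir = out / "gene_trees"
    tdir.mkdir(exist_ok=True)
    for tid, nwk in gt.trees:
        (tdir / f"{tid}.nwk").write_text(nwk + "\n")
    (out / "truth_gene_trees.json").write_text(json.dumps(gt.truth, indent=2, sort_keys=True))

    print(f"simulated scenario (seed {args.seed}) -> {out}")
    print(
        f"  {len(ds.svs)} assembly SVs ({len(ds.truth['planted_te'])} planted het-TE), "
        f"{len(bm.mutations)} branch mutations, {len(hits)} dated repeat copies,"
    )
    print(f"  {len(ces)} conserved elements across {len(DEPTH_SPECIES)} species, 200 gene trees")


if __name__ == "__main__":
    main()
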