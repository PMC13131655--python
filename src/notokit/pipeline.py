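"""End-to-end orchestration of the synthetic analysis scenario.

``run_pipeline`` generates every input with planted truth, runs the six
analysis stages in dependency order, and writes plain-text artifacts plus
a run manifest (seed, config hash, package version) into the output
directory.  Re-running with an identical config and seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .afgp import detect_alternating_arrays, detect_duplication_motif, validate_gene
from .branch_dynamics import (
    attribute_te_insertions,
    merge_lifted_insertions,
    net_gain_rates,
    rate_curve,
)
from .conserved import assign_feature, classify_ancestry, link_cne_to_gene, merge_ces
from .hapvar import (
    compare_sv_callsets,
    detect_het_te_insertions,
    divergence_shift_test,
    hemizygous_fraction,
    insertion_context,
    sv_feature_association,
)
from .intervals import GenomicInterval
from .io import (
    read_dated_tree,
    write_branch_mutations,
    write_repeat_table,
    write_sv_table,
)
from .phylo import monophyly_sister_filter, subtract_background
from .synthetic import (
    default_layout,
    simulate_afgp_locus,
    simulate_branch_mutations,
    simulate_depth_tracks,
    simulate_diploid_sv_dataset,
    simulate_gene_trees,
    simulate_repeat_divergences,
)
from .te_dynamics import NeutralRateConfig, coverage_by_class, dated_landscape, landscape_frame

__all__ = ["RunConfig", "run_pipeline", "verify_manifest"]

#: 5-taxon dated toy tree: temperate outgroups + a focal Antarctic clade.
DEFAULT_TREE = "(((HarAnt:6.86,PogAlb:6.86):3.84,DisMaw:10.7):7.0,EleMac:17.7);"


@dataclass
class RunConfig:
    """All pipeline thresholds with their standard defaults."""

    seed: int = 1
    output_dir: str = "notokit_run"
    min_reciprocal: float = 0.75
    lift_merge_gap_bp: int = 100
    ce_merge_gap_bp: int = 5
    min_cov: float = 0.75
    flank_bp: int = 50_000
    context_flank_bp: int = 2_500
    min_sv_size_bp: int = 50
    neutral_rate: float = 3.2e-3
    divisor_mode: str = "2r"
    landscape_bin_my: float = 1.0
    n_te_insertions: int = 500
    n_other_svs: int = 500
    n_ces: int = 300
    n_gene_trees: int = 60
    afgp_units: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        payload = {k: v for k, v in self.to_dict().items() if k != "output_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _write_tsv(path: Path, header: list[str], rows, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# notokit config_hash={config_hash}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage on a synthetic scenario; returns the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.content_hash()
    seed = config.seed
    summary: dict = {}

    # stage 0: simulate -----------------------------------------------------
    layout = default_layout()
    ds = simulate_diploid_sv_dataset(
        layout,
        n_te_insertions=config.n_te_insertions,
        n_other_svs=config.n_other_svs,
        seed=seed,
    )
    write_sv_table(out / "svs.tsv", ds.svs)
    write_repeat_table(out / "repeats_hap1.tsv", ds.repeats_hap1)
    (out / "truth_diploid.json").write_text(json.dumps(ds.truth, indent=2, sort_keys=True))

    # stage 1: haplotype variation ------------------------------------------
    hemi = hemizygous_fraction(ds.svs, layout.total_bp)
    matches = detect_het_te_insertions(
        ds.svs, ds.repeats_hap1, ds.repeats_hap2, min_reciprocal=config.min_reciprocal
    )
    labels, context_counts = insertion_context(
        [m.sv for m in matches], ds.genes, flank_bp=config.context_flank_bp
    )
    support = compare_sv_callsets(
        ds.svs, ds.read_svs, min_size=config.min_sv_size_bp
    )
    fit = sv_feature_association(
        ds.svs, layout, ds.features, flank_bp=config.flank_bp, seed=seed
    )
    het_div = [m.hit.divergence_pct for m in matches]
    matched_ids = {id(m.hit) for m in matches}
    other_div = [
        h.divergence_pct for h in ds.repeats_hap1 + ds.repeats_hap2 if id(h) not in matched_ids
    ]
    shift = divergence_shift_test(het_div, other_div)
    fit.table.to_csv(out / "association.tsv", sep="\t", index=False)
    _write_tsv(
        out / "het_te_matches.tsv",
        ["chrom", "start", "sv_type", "family", "class", "context"],
        [
            (
                m.sv.ref_interval.chrom,
                m.sv.ref_interval.start,
                m.sv.sv_type,
                m.hit.family,
                m.hit.class_label,
                lab,
            )
            for m, lab in zip(matches, labels)
        ],
        h,
    )
    summary["hapvar"] = {
        "hemizygous_fraction": hemi,
        "n_het_te": len(matches),
        "context_counts": context_counts,
        "support_pct": support.percentages,
        "divergence_shift_p": shift.p_value,
        "association_method": fit.method,
    }

    # stage 2: dated landscape ----------------------------------------------
    cfg = NeutralRateConfig(rate=config.neutral_rate, divisor_mode=config.divisor_mode)
    repeats, land_truth = simulate_repeat_divergences(
        rate=config.neutral_rate, divisor_mode=config.divisor_mode, seed=seed
    )
    bins = dated_landscape(repeats, cfg, bin_width_my=config.landscape_bin_my)
    landscape_frame(bins).to_csv(out / "landscape.tsv", sep="\t", index=False)
    pct_class, _ = coverage_by_class(repeats, layout.total_bp)
    summary["landscape"] = {
        "n_bins": len(bins),
        "total_bp": sum(b.total_bp for b in bins),
        "coverage_pct_by_class": pct_class,
    }

    # stage 3: branch dynamics ----------------------------------------------
    tree = read_dated_tree(DEFAULT_TREE)
    bm = simulate_branch_mutations(tree, seed=seed)
    write_branch_mutations(out / "branch_mutations.tsv", bm.mutations)
    rates = net_gain_rates(bm.mutations, tree)
    merged = merge_lifted_insertions(bm.mutations, max_gap=config.lift_merge_gap_bp)
    attributed = attribute_te_insertions(
        merged, bm.repeats, tree, min_reciprocal=config.min_reciprocal
    )
    curve = rate_curve(attributed, tree, "HarAnt")
    curve.to_csv(out / "rate_curve_HarAnt.tsv", sep="\t", index=False)
    _write_tsv(
        out / "branch_rates.tsv",
        ["branch_id", "ins_bp", "del_bp", "net_bp", "duration_my", "net_rate_mb_per_my", "te_insertions", "te_per_my"],
        [
            (
                bid,
                r.ins_bp,
                r.del_bp,
                r.net_bp,
                f"{r.duration_my:g}",
                f"{r.net_rate_mb_per_my:.6f}",
                attributed[bid].te_insertions,
                f"{attributed[bid].te_per_my:.4f}",
            )
            for bid, r in sorted(rates.items())
        ],
        h,
    )
    summary["branch_dynamics"] = {
        "branches": len(rates),
        "total_ins_bp": sum(r.ins_bp for r in rates.values()),
        "total_del_bp": sum(r.del_bp for r in rates.values()),
        "te_insertions": sum(r.te_insertions for r in attributed.values()),
    }

    # stage 4: conserved elements -------------------------------------------
    rng_layout = default_layout(with_gaps=False)
    ce_rng_labels = ["ancestral", "clade_specific", "other"]
    import numpy as np

    ce_rng = np.random.default_rng([seed, 71])
    ces_raw = []
    ce_truth = []
    cursor = 0
    for i in range(config.n_ces):
        chrom = rng_layout.chroms[i % len(rng_layout.chroms)]
        L = int(ce_rng.integers(60, 400))
        s = cursor + int(ce_rng.integers(50, 500))
        cursor = s + L
        if cursor > rng_layout.chrom_lengths[chrom]:
            break
        ces_raw.append(GenomicInterval(chrom, s, s + L))
        ce_truth.append(ce_rng_labels[int(ce_rng.integers(3))])
    species = ["EleMac", "CotGob", "DisMaw", "PogAlb", "HarAnt2"]
    clade = ["DisMaw", "PogAlb", "HarAnt2"]
    tracks = simulate_depth_tracks(ces_raw, ce_truth, species, clade, min_cov=config.min_cov, seed=seed)
    merged_ces = merge_ces(ces_raw, max_gap=config.ce_merge_gap_bp)
    classified = classify_ancestry(merged_ces, tracks, species, clade, min_cov=config.min_cov)
    featured = assign_feature(classified, ds.genes)
    linked = link_cne_to_gene([c for c in featured if c.feature == "intergenic"], ds.genes)
    _write_tsv(
        out / "conserved_elements.tsv",
        ["chrom", "start", "end", "ancestry", "feature"],
        [
            (c.interval.chrom, c.interval.start, c.interval.end, c.ancestry, c.feature)
            for c in featured
        ],
        h,
    )
    summary["conserved_elements"] = {
        "n_elements": len(featured),
        "ancestry_counts": {
            lab: sum(1 for c in featured if c.ancestry == lab) for lab in ce_rng_labels
        },
        "n_linked_cnes": sum(1 for c in linked if c.linked_genes),
    }

    # stage 5: gene-tree filter ---------------------------------------------
    gt = simulate_gene_trees(
        config.n_gene_trees,
        clade_taxa=clade,
        sister_taxon="EleMac",
        outgroup_taxa=["CotGob", "GasAcu", "TakRub"],
        seed=seed,
    )
    decisions = monophyly_sister_filter(gt.trees, clade, "EleMac")
    kept = {d.tree_id for d in decisions if d.keep}
    background = {d.tree_id for d in decisions[: len(decisions) // 10]}
    focal_minus_bg = subtract_background(kept, background)
    _write_tsv(
        out / "tree_filter.tsv",
        ["tree_id", "keep", "reasons"],
        [(d.tree_id, int(d.keep), ";".join(d.reasons) or ".") for d in decisions],
        h,
    )
    summary["tree_filter"] = {
        "n_trees": len(decisions),
        "n_kept": len(kept),
        "n_after_background_subtraction": len(focal_minus_bg),
    }

    # stage 6: afgp locus ----------------------------------------------------
    sim = simulate_afgp_locus(
        n_units=config.afgp_units,
        pseudogene_events={"afgp1": "drop_exon1", "afgp4": "frameshift"},
        seed=seed,
    )
    validations = [validate_gene(g) for g in sim.genes]
    runs = detect_alternating_arrays(sim.layout)
    motif = detect_duplication_motif(sim.layout)
    _write_tsv(
        out / "afgp_genes.tsv",
        ["gene_id", "strand", "type", "status", "reasons"],
        [
            (g.gene_id, g.strand, g.gene_type, v.status, ";".join(v.reasons) or ".")
            for g, v in zip(sim.genes, validations)
        ],
        h,
    )
    summary["afgp"] = {
        "n_genes": len(sim.genes),
        "n_pseudogenes": sum(1 for v in validations if v.status == "pseudogene"),
        "longest_alternating_run": max((r.length for r in runs), default=0),
        "duplication_unit_copies": motif.copies if motif else 0,
    }

    manifest = {
        "package": "notokit",
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "config_hash": h,
        "stages": list(summary),
    }
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return out


def verify_manifest(output_dir: str | Path) -> bool:
    """Recompute the config hash from the serialized config and compare."""
    out = Path(output_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    config = RunConfig(**yaml.safe_load((out / "config.yaml").read_text()))
    return manifest["config_hash"] == config.content_hash()
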