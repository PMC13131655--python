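"""Generator contracts: determinism, planted structure, moment checks."""

import numpy as np
import pytest
from scipy import stats as sps

from notokit.intervals import merge_within, passes_reciprocal
from notokit.io import read_dated_tree
from notokit.synthetic import (
    default_layout,
    simulate_afgp_locus,
    simulate_branch_mutations,
    simulate_depth_tracks,
    simulate_diploid_sv_dataset,
    simulate_gene_trees,
    simulate_repeat_divergences,
)

TREE = read_dated_tree("(((A:2,B:2):3,C:5):2,D:7);")


class TestDiploidDataset:
    def test_deterministic(self):
        a = simulate_diploid_sv_dataset(n_te_insertions=30, n_other_svs=30, seed=9)
        b = simulate_diploid_sv_dataset(n_te_insertions=30, n_other_svs=30, seed=9)
        assert a.svs == b.svs
        assert a.repeats_hap1 == b.repeats_hap1
        assert a.read_svs == b.read_svs

    def test_zero_jitter_all_planted_pass_rule(self):
        ds = simulate_diploid_sv_dataset(n_te_insertions=60, n_other_svs=0, seed=2)
        hits = {"DEL": ds.repeats_hap1, "INS": ds.repeats_hap2}
        for sv in ds.svs:
            span = sv.span()
            assert any(
                passes_reciprocal(span, h.interval) for h in hits[sv.sv_type]
            ), f"planted {sv.sv_type} without matching repeat"

    def test_uniform_placement_without_effects(self):
        # chi-square GOF over chromosomes at n=5000 midpoints
        ds = simulate_diploid_sv_dataset(
            n_te_insertions=0, n_other_svs=5000, seed=4
        )
        layout = ds.layout
        counts = {c: 0 for c in layout.chroms}
        for sv in ds.svs:
            counts[sv.ref_interval.chrom] += 1
        observed = np.array([counts[c] for c in layout.chroms])
        lens = np.array([layout.chrom_lengths[c] for c in layout.chroms], dtype=float)
        expected = len(ds.svs) * lens / lens.sum()
        stat = ((observed - expected) ** 2 / expected).sum()
        p = sps.chi2.sf(stat, len(observed) - 1)
        assert p > 0.01

    def test_truth_lists_every_planted_record(self):
        ds = simulate_diploid_sv_dataset(n_te_insertions=25, n_other_svs=35, seed=5)
        assert len(ds.truth["planted_te"]) == 25
        assert len(ds.truth["planted_other"]) == 35
        assert len(ds.truth["read_support_labels"]) == len(ds.svs)


class TestBranchMutations:
    def test_deletion_rate_zero_means_net_equals_gross(self):
        sim = simulate_branch_mutations(TREE, del_rate_bp_per_my=0.0, seed=3)
        assert all(m.kind == "insertion" for m in sim.mutations)

    def test_realized_bp_tracks_rate(self):
        # mean over 20 replicates within 3 SD of the compound-Poisson total
        rate, mean_bp = 500_000.0, 1_000
        totals = []
        for rep in range(20):
            sim = simulate_branch_mutations(
                TREE, ins_rate_bp_per_my=rate, del_rate_bp_per_my=0.0,
                mean_event_bp=mean_bp, seed=rep,
            )
            totals.append(sum(m.bp for m in sim.mutations if m.branch_id == "A"))
        dur = TREE.durations["A"]
        lam = rate * dur / mean_bp
        # event size ~ U[0.5, 1.5] * mean: Var S = (mean^2)/12, E S^2 accordingly
        var_total = lam * (mean_bp**2 + mean_bp**2 / 12)
        sd_mean = np.sqrt(var_total / 20)
        assert abs(np.mean(totals) - rate * dur) < 3 * sd_mean

    def test_fragments_merge_back_to_event_count(self):
        sim = simulate_branch_mutations(TREE, seed=7)
        lifted = [m for m in sim.mutations if m.kind == "insertion"]
        merged = merge_within(
            [m.lifted_interval for m in lifted],
            max_gap=100,
            keys=[(m.branch_id, m.event_id) for m in lifted],
        )
        expected = sum(b["n_events"] for b in sim.truth["per_branch"].values())
        assert len(merged) == expected


class TestDepthTracks:
    def test_planted_ancestry_margins(self, rng):
        from notokit.intervals import GenomicInterval

        ces = [GenomicInterval("c", i * 1000, i * 1000 + 200) for i in range(60)]
        labels = [["ancestral", "clade_specific", "other"][i % 3] for i in range(60)]
        species = ["s1", "s2", "s3", "s4"]
        clade = ["s3", "s4"]
        tracks = simulate_depth_tracks(ces, labels, species, clade, seed=11)
        for iv, lab in zip(ces, labels):
            cov = {sp: tracks[sp].covered_fraction(iv) for sp in species}
            if lab == "ancestral":
                assert all(v >= 0.75 for v in cov.values())
            elif lab == "clade_specific":
                assert all(cov[sp] >= 0.75 for sp in clade)
                assert any(cov[sp] < 0.75 for sp in ("s1", "s2"))
            else:
                assert any(cov[sp] < 0.75 for sp in clade)


class TestRepeatDivergences:
    def test_component_at_zero_gives_zero_divergence_cluster(self):
        hits, truth = simulate_repeat_divergences(
            n=300, age_components=((0.0, 0.0, 1.0),), seed=1
        )
        assert all(h.divergence_pct == 0.0 for h in hits)

    def test_deterministic(self):
        a, _ = simulate_repeat_divergences(n=100, seed=5)
        b, _ = simulate_repeat_divergences(n=100, seed=5)
        assert a == b

    def test_divergence_inverts_dating_formula(self):
        hits, truth = simulate_repeat_divergences(
            n=50, age_components=((5.0, 0.0, 1.0),), rate=3.2e-3, divisor_mode="2r", seed=2
        )
        # age 5 MY -> K = 5 * 2 * 3.2e-3 * 100 = 3.2%
        assert all(h.divergence_pct == pytest.approx(3.2) for h in hits)


class TestAfgpLocus:
    def test_unit_structure(self):
        sim = simulate_afgp_locus(n_units=3, n_chimeric=0, seed=3)
        afgp = [g for g in sim.genes if g.gene_type == "afgp"]
        assert len(afgp) == 12
        strands = "".join(g.strand for g in afgp)
        assert strands == "+-+-" * 3

    def test_planted_pseudogenes_recorded(self):
        events = {"afgp2": "frameshift", "afgp5": "strip_terminal"}
        sim = simulate_afgp_locus(n_units=2, pseudogene_events=events, seed=1)
        assert sim.truth["pseudogenes"] == ["afgp2", "afgp5"]

    def test_chimeric_only_event_rejected_on_plain_gene(self):
        with pytest.raises(ValueError):
            simulate_afgp_locus(n_units=1, pseudogene_events={"afgp1": "delete_tlp_exons"}, seed=1)


class TestGeneTrees:
    def test_truth_recovered_by_filter(self):
        from notokit.phylo import monophyly_sister_filter

        clade = ["c1", "c2", "c3"]
        sim = simulate_gene_trees(
            40, clade, "Emac", ["o1", "o2", "o3"], p_monophyletic=0.5, seed=8
        )
        decisions = monophyly_sister_filter(sim.trees, clade, "Emac")
        for d in decisions:
            assert d.keep == sim.truth[d.tree_id]["keep"], (
                d.tree_id,
                sim.truth[d.tree_id]["mode"],
                d.reasons,
            )
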