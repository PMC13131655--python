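"""Conserved elements: merging, ancestry by depth, features, gene links."""

import numpy as np
import pytest

from notokit.conserved import (
    ConservedElement,
    assign_feature,
    classify_ancestry,
    link_cne_to_gene,
    merge_ces,
)
from notokit.intervals import GenomicInterval
from notokit.io import DepthTrack, GeneModel
from notokit.synthetic import simulate_depth_tracks

from conftest import bitmap_cover


def GI(s, e, chrom="c"):
    return GenomicInterval(chrom, s, e)


def _track(sp, ivs):
    return DepthTrack(sp, tuple(ivs))


class TestMergeCes:
    def test_gap_four_merges(self):
        out = merge_ces([GI(0, 10), GI(14, 20)], max_gap=5)
        assert [c.interval for c in out] == [GI(0, 20)]

    def test_gap_five_does_not_merge(self):
        out = merge_ces([GI(0, 10), GI(15, 20)], max_gap=5)
        assert len(out) == 2

    def test_idempotent(self, rng):
        ivs = [GI(int(s), int(s) + int(l)) for s, l in zip(rng.integers(0, 5000, 100), rng.integers(1, 40, 100))]
        once = merge_ces(ivs)
        twice = merge_ces(once)
        assert [c.interval for c in once] == [c.interval for c in twice]


class TestAncestry:
    SPECIES = ["out1", "out2", "cryo1", "cryo2"]
    CLADE = ["cryo1", "cryo2"]

    def classify_one(self, tracks, iv=None):
        iv = iv or GI(0, 100)
        (ce,) = classify_ancestry([iv], tracks, self.SPECIES, self.CLADE)
        return ce

    def test_all_covered_is_ancestral(self):
        tracks = {sp: _track(sp, [GI(0, 80)]) for sp in self.SPECIES}
        assert self.classify_one(tracks).ancestry == "ancestral"

    def test_boundary_75_inclusive(self):
        tracks = {sp: _track(sp, [GI(0, 75)]) for sp in self.SPECIES}
        assert self.classify_one(tracks).ancestry == "ancestral"

    def test_outgroup_just_below_means_clade_specific(self):
        tracks = {
            "out1": _track("out1", [GI(0, 74)]),
            "out2": _track("out2", [GI(0, 100)]),
            "cryo1": _track("cryo1", [GI(0, 100)]),
            "cryo2": _track("cryo2", [GI(0, 100)]),
        }
        assert self.classify_one(tracks).ancestry == "clade_specific"

    def test_clade_member_below_is_other(self):
        tracks = {
            "out1": _track("out1", [GI(0, 100)]),
            "out2": _track("out2", [GI(0, 100)]),
            "cryo1": _track("cryo1", [GI(0, 50)]),
            "cryo2": _track("cryo2", [GI(0, 100)]),
        }
        assert self.classify_one(tracks).ancestry == "other"

    def test_missing_track_rejected(self):
        tracks = {sp: _track(sp, []) for sp in self.SPECIES[:-1]}
        with pytest.raises(KeyError):
            classify_ancestry([GI(0, 10)], tracks, self.SPECIES, self.CLADE)

    def test_matches_per_base_counting_oracle(self, rng):
        ces = []
        for i in range(300):
            s = int(rng.integers(0, 9_000))
            ces.append(GI(s, s + int(rng.integers(10, 200))))
        tracks = {}
        for sp in self.SPECIES:
            ivs = [
                GI(int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 9_500, 400), rng.integers(1, 150, 400))
            ]
            tracks[sp] = _track(sp, ivs)
        out = classify_ancestry(ces, tracks, self.SPECIES, self.CLADE)
        bitmaps = {sp: bitmap_cover(tracks[sp].intervals, "c", 10_000) for sp in self.SPECIES}
        for ce in out:
            iv = ce.interval
            cov = {sp: bitmaps[sp][iv.start : iv.end].sum() / iv.length for sp in self.SPECIES}
            if all(cov[sp] >= 0.75 for sp in self.SPECIES):
                expected = "ancestral"
            elif all(cov[sp] >= 0.75 for sp in self.CLADE) and any(
                cov[sp] < 0.75 for sp in ("out1", "out2")
            ):
                expected = "clade_specific"
            else:
                expected = "other"
            assert ce.ancestry == expected
            assert ce.coverage == pytest.approx(cov)

    def test_planted_truth_recovered(self):
        ces = [GI(i * 500, i * 500 + 120) for i in range(90)]
        labels = [["ancestral", "clade_specific", "other"][i % 3] for i in range(90)]
        tracks = simulate_depth_tracks(ces, labels, self.SPECIES, self.CLADE, seed=4)
        out = classify_ancestry(ces, tracks, self.SPECIES, self.CLADE)
        assert [c.ancestry for c in out] == labels


class TestAssignFeature:
    GENES = [
        GeneModel(
            "gplus",
            GenomicInterval("c", 50_000, 60_000, "+"),
            exons=(GenomicInterval("c", 50_000, 50_400, "+"), GenomicInterval("c", 59_000, 60_000, "+")),
        ),
    ]

    def _one(self, s, e):
        (out,) = assign_feature([ConservedElement(interval=GI(s, e))], self.GENES)
        return out.feature

    def test_exon(self):
        assert self._one(50_100, 50_200) == "exon"

    def test_promoter_upstream_of_tss(self):
        # midpoint 500 bp upstream of the + strand TSS at 50,000
        assert self._one(49_450, 49_550) == "promoter"

    def test_tts_window(self):
        assert self._one(60_050, 60_150) == "TTS"

    def test_intron(self):
        assert self._one(55_000, 55_100) == "intron"

    def test_intergenic(self):
        assert self._one(10_000, 10_100) == "intergenic"

    def test_labels_partition(self, rng):
        ces = [ConservedElement(interval=GI(int(s), int(s) + 50)) for s in rng.integers(0, 99_000, 200)]
        out = assign_feature(ces, self.GENES)
        assert all(c.feature in ("exon", "promoter", "TTS", "intron", "intergenic") for c in out)
        assert len(out) == 200


class TestLinkCne:
    GENES = [
        GeneModel("left", GenomicInterval("c", 0, 1_000, "+")),
        GeneModel("right", GenomicInterval("c", 3_000, 4_000, "+")),
    ]

    def test_nearest_gene(self):
        (out,) = link_cne_to_gene([ConservedElement(interval=GI(1_100, 1_200))], self.GENES)
        assert out.linked_genes == ("left",)

    def test_equidistant_reports_both(self):
        # CNE [1950, 2050): 950 bp from both transcript bounds
        (out,) = link_cne_to_gene([ConservedElement(interval=GI(1_950, 2_050))], self.GENES)
        assert out.linked_genes == ("left", "right")

    def test_no_genes_on_chromosome_unlinked(self):
        (out,) = link_cne_to_gene(
            [ConservedElement(interval=GenomicInterval("other", 0, 50))], self.GENES
        )
        assert out.linked_genes == ()

    def test_matches_exhaustive_oracle(self, rng):
        genes = [
            GeneModel(f"g{i}", GenomicInterval("c", int(s), int(s) + 500, "+"))
            for i, s in enumerate(rng.choice(np.arange(0, 50_000, 1_000), 20, replace=False))
        ]
        cnes = [ConservedElement(interval=GI(int(s), int(s) + 30)) for s in rng.integers(0, 49_000, 100)]
        out = link_cne_to_gene(cnes, genes)
        for ce in out:
            iv = ce.interval
            dists = {}
            for g in genes:
                gi = g.interval
                d = 0 if min(iv.end, gi.end) > max(iv.start, gi.start) else max(gi.start - iv.end, iv.start - gi.end, 0)
                dists[g.gene_id] = d
            dmin = min(dists.values())
            assert set(ce.linked_genes) == {g for g, d in dists.items() if d == dmin}
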