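"""Conserved-element post-processing.

Merges raw conserved elements (CEs), classifies each element's ancestry
from per-species alignment-depth tracks (ancestral vs cryonotothenioid-
specific vs other), assigns elements to genomic features, and links
intergenic elements (CNEs) to their nearest gene.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, replace

from .intervals import CoverageIndex, GenomicInterval, merge_within
from .io import DepthTrack, GeneModel

__all__ = [
    "ConservedElement",
    "merge_ces",
    "classify_ancestry",
    "assign_feature",
    "link_cne_to_gene",
]

ANCESTRY_LABELS = ("ancestral", "clade_specific", "other")
FEATURE_LABELS = ("exon", "promoter", "TTS", "intron", "intergenic")


@dataclass(frozen=True)
class ConservedElement:
    """A conserved interval with per-species coverage and labels."""

    interval: GenomicInterval
    coverage: Mapping[str, float] | None = None
    ancestry: str | None = None
    feature: str | None = None
    linked_genes: tuple[str, ...] = ()


def merge_ces(
    ces: Sequence[GenomicInterval | ConservedElement], max_gap: int = 5
) -> list[ConservedElement]:
    """Merge elements closer than ``max_gap`` bp (strict) into single elements.

    Labels and coverages of the inputs are discarded — downstream stages
    recompute per-species fractions on the merged interval.
    """
    ivs = [c.interval if isinstance(c, ConservedElement) else c for c in ces]
    return [ConservedElement(interval=m.interval) for m in merge_within(ivs, max_gap)]


def classify_ancestry(
    ces: Sequence[ConservedElement | GenomicInterval],
    tracks: Mapping[str, DepthTrack],
    all_species: Sequence[str],
    focal_clade: Sequence[str],
    min_cov: float = 0.75,
) -> list[ConservedElement]:
    """Label each element ancestral / clade_specific / other by coverage.

    * ``ancestral``: covered over at least ``min_cov`` of its length by
      every species (threshold inclusive);
    * ``clade_specific``: >= ``min_cov`` for every focal-clade member AND
      < ``min_cov`` for at least one non-clade species;
    * ``other``: everything else.
    """
    focal = set(focal_clade)
    missing = [sp for sp in all_species if sp not in tracks]
    if missing:
        raise KeyError(f"missing depth tracks for species: {missing}")
    if not focal.issubset(set(all_species)):
        raise ValueError("focal clade must be a subset of all_species")
    out = []
    for ce in ces:
        iv = ce.interval if isinstance(ce, ConservedElement) else ce
        cov = {sp: tracks[sp].covered_fraction(iv) for sp in all_species}
        if all(cov[sp] >= min_cov for sp in all_species):
            label = "ancestral"
        elif all(cov[sp] >= min_cov for sp in focal) and any(
            cov[sp] < min_cov for sp in all_species if sp not in focal
        ):
            label = "clade_specific"
        else:
            label = "other"
        base = ce if isinstance(ce, ConservedElement) else ConservedElement(interval=iv)
        out.append(replace(base, coverage=cov, ancestry=label))
    return out


def assign_feature(
    ces: Sequence[ConservedElement],
    genes: Sequence[GeneModel],
    promoter_upstream: int = 2000,
    promoter_downstream: int = 200,
    tts_window: int = 200,
) -> list[ConservedElement]:
    """Assign each element to exon / promoter / TTS / intron / intergenic.

    Assignment is decided at the element midpoint with priority
    exon > promoter > TTS > intron > intergenic.  Promoter and TTS windows
    are strand-aware: the promoter spans ``promoter_upstream`` bp upstream
    through ``promoter_downstream`` bp downstream of the TSS; the TTS
    window spans +/- ``tts_window`` around the termination site.
    """
    exon_idx = CoverageIndex([e for g in genes for e in g.exons])
    gene_idx = CoverageIndex([g.interval for g in genes])
    promoters = []
    tts_ivs = []
    for g in genes:
        if g.strand == "-":
            promoters.append((g.interval.chrom, g.tss - promoter_downstream, g.tss + promoter_upstream + 1))
            tts_ivs.append((g.interval.chrom, g.tts - tts_window, g.tts + tts_window + 1))
        else:
            promoters.append((g.interval.chrom, g.tss - promoter_upstream, g.tss + promoter_downstream + 1))
            tts_ivs.append((g.interval.chrom, g.tts - tts_window, g.tts + tts_window + 1))
    prom_idx = CoverageIndex(
        [GenomicInterval(c, max(0, s), e) for c, s, e in promoters if e > max(0, s)]
    )
    tts_idx = CoverageIndex(
        [GenomicInterval(c, max(0, s), e) for c, s, e in tts_ivs if e > max(0, s)]
    )
    out = []
    for ce in ces:
        mid = ce.interval.midpoint()
        chrom = ce.interval.chrom
        if exon_idx.covered_bp(chrom, mid, mid + 1) > 0:
            label = "exon"
        elif prom_idx.covered_bp(chrom, mid, mid + 1) > 0:
            label = "promoter"
        elif tts_idx.covered_bp(chrom, mid, mid + 1) > 0:
            label = "TTS"
        elif gene_idx.covered_bp(chrom, mid, mid + 1) > 0:
            label = "intron"
        else:
            label = "intergenic"
        out.append(replace(ce, feature=label))
    return out


def link_cne_to_gene(
    cnes: Sequence[ConservedElement],
    genes: Sequence[GeneModel],
    max_distance: int | None = None,
) -> list[ConservedElement]:
    """Link each intergenic element to its nearest gene(s) by bp distance.

    Distance is measured to the transcript bounds; exact ties report every
    tied gene.  Elements with no gene on their chromosome (or none within
    ``max_distance``) stay unlinked.
    """
    per_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        per_chrom.setdefault(g.interval.chrom, []).append(g)
    out = []
    for ce in cnes:
        iv = ce.interval
        cands = per_chrom.get(iv.chrom, [])
        best_d: int | None = None
        best: list[str] = []
        for g in cands:
            gi = g.interval
            if iv.overlap_bp(gi) > 0:
                d = 0
            else:
                d = max(gi.start - iv.end, iv.start - gi.end, 0)
            if max_distance is not None and d > max_distance:
                continue
            if best_d is None or d < best_d:
                best_d, best = d, [g.gene_id]
            elif d == best_d:
                best.append(g.gene_id)
        out.append(replace(ce, linked_genes=tuple(sorted(best))))
    return out
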