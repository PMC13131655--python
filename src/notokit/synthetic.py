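"""Synthetic-data generators with known planted truth.

Every pipeline stage is testable without the real genomes: these
generators emulate the *statistical structure* the analyses assume —
diploid haplotype pairs with planted heterozygous TE insertions and SVs
whose placement depends on local feature densities, branch-mutation tables
under per-branch insertion/deletion rates on a dated tree, repeat tables
with divergences drawn from stated activity peaks, alignment-depth tracks
with planted conserved-element ancestry, gene trees with and without
planted clade monophyly, and token-level afgp-locus layouts with planted
duplication units and pseudogenization events.

Each generator is a deterministic function of (parameters, seed).  A
single root seed is threaded through per-component sub-streams, so adding
a generator never perturbs the draws of another.
"""

from __future__ import annotations

import json
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .afgp import AfgpGeneModel, LocusLayout, LocusToken
from .intervals import (
    CoverageIndex,
    GenomeLayout,
    GenomicInterval,
    PlacementError,
    passes_reciprocal,
)
from .io import BranchMutation, DatedTree, DepthTrack, GeneModel, RepeatHit, SVRecord

__all__ = [
    "default_layout",
    "DiploidSVDataset",
    "simulate_diploid_sv_dataset",
    "BranchMutationSim",
    "simulate_branch_mutations",
    "simulate_depth_tracks",
    "simulate_repeat_divergences",
    "AfgpLocusSim",
    "simulate_afgp_locus",
    "GeneTreeSim",
    "simulate_gene_trees",
]

# fixed stream ids: one per generator component
_STREAMS = {
    "features": 11,
    "het_te": 12,
    "other_sv": 13,
    "reads": 14,
    "branch": 21,
    "depth": 31,
    "landscape": 41,
    "afgp": 51,
    "trees": 61,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


def default_layout(
    n_chroms: int = 20,
    chrom_len: int = 1_000_000,
    gap_bp: int = 5_000,
    with_gaps: bool = True,
) -> GenomeLayout:
    """A small many-chromosome layout standing in for a fish genome.

    20 x 1 Mb keeps every stage fast while leaving room for 50-kb flank
    windows; one assembly gap per chromosome (placed at 60% of its length)
    exercises gap exclusion and gap-distance predictors.
    """
    lengths = {f"chr{i + 1:02d}": chrom_len for i in range(n_chroms)}
    gaps = ()
    if with_gaps:
        gaps = tuple(
            GenomicInterval(c, int(0.6 * chrom_len), int(0.6 * chrom_len) + gap_bp)
            for c in lengths
        )
    return GenomeLayout(chrom_lengths=lengths, gaps=gaps)


# ---------------------------------------------------------------------------
# diploid SV dataset


@dataclass
class DiploidSVDataset:
    layout: GenomeLayout
    svs: list[SVRecord]
    read_svs: list[SVRecord]
    repeats_hap1: list[RepeatHit]
    repeats_hap2: list[RepeatHit]
    genes: list[GeneModel]
    features: dict[str, list[GenomicInterval]]
    truth: dict
    seed: int


_TE_CLASS_P = {"DNA": 0.30, "LINE": 0.35, "LTR": 0.25, "other": 0.10}
_HET_CLASS_P = {"LINE": 0.40, "LTR": 0.30, "DNA": 0.25, "other": 0.05}


def _draw_lengths(rng, n, mean_log, sigma, lo, hi):
    return np.clip(np.exp(rng.normal(mean_log, sigma, n)).astype(int), lo, hi)


def _background_repeats(rng, layout, fraction, hap):
    """Roughly ``fraction`` of the genome in background repeat copies."""
    hits = []
    fam_by_class = {
        "DNA": [f"hAT-{i}" for i in range(1, 5)],
        "LINE": [f"L2-{i}" for i in range(1, 9)],
        "LTR": [f"Gypsy-{i}" for i in range(1, 5)],
        "other": ["Unknown-1", "Unknown-2"],
    }
    classes = list(_TE_CLASS_P)
    probs = np.array([_TE_CLASS_P[c] for c in classes])
    for chrom, clen in layout.chrom_lengths.items():
        mean_len = 1_300
        n = int(fraction * clen / mean_len)
        lengths = _draw_lengths(rng, n, math.log(1_000), 0.8, 200, 20_000)
        starts = rng.integers(0, clen - lengths)
        cls = rng.choice(len(classes), size=n, p=probs)
        div = rng.gamma(4.0, 1.5, n)  # background: mostly older copies
        scores = rng.integers(200, 2_000, n)
        for s, L, c, d, sc in zip(starts, lengths, cls, div, scores):
            label = classes[c]
            fam = fam_by_class[label][int(rng.integers(len(fam_by_class[label])))]
            hits.append(
                RepeatHit(
                    interval=GenomicInterval(chrom, int(s), int(s + L)),
                    family=fam,
                    class_label=label,
                    divergence_pct=float(d),
                    score=float(sc),
                )
            )
    return hits


def _background_genes(rng, layout, per_mb=20):
    genes = []
    k = 0
    for chrom, clen in layout.chrom_lengths.items():
        n = max(1, int(per_mb * clen / 1_000_000))
        taken: list[tuple[int, int]] = []
        tries = 0
        while len(taken) < n and tries < 50 * n:
            tries += 1
            span = int(np.clip(rng.normal(14_000, 5_000), 2_000, 40_000))
            s = int(rng.integers(0, clen - span))
            if any(s < e and s + span > b for b, e in taken):
                continue
            taken.append((s, s + span))
        for s, e in sorted(taken):
            k += 1
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(3, 10))
            cuts = np.sort(rng.choice(np.arange(s + 100, e - 100), size=2 * n_ex - 2, replace=False))
            bounds = [s, *cuts.tolist(), e]
            exons = [
                GenomicInterval(chrom, bounds[2 * i], bounds[2 * i + 1], strand)
                for i in range(n_ex)
            ]
            genes.append(
                GeneModel(
                    gene_id=f"g{k:05d}",
                    interval=GenomicInterval(chrom, s, e, strand),
                    exons=tuple(exons),
                )
            )
    return genes


def simulate_diploid_sv_dataset(
    layout: GenomeLayout | None = None,
    n_te_insertions: int = 500,
    n_other_svs: int = 500,
    effect_log_odds: Mapping[str, float] | None = None,
    boundary_jitter_frac: float = 0.0,
    flank_bp: int = 50_000,
    read_support: tuple[float, float] = (0.666, 0.017),
    seed: int = 0,
) -> DiploidSVDataset:
    """A diploid haplotype-comparison scenario with planted truth.

    Plants ``n_te_insertions`` heterozygous TE insertions (each backed by a
    repeat copy at reciprocal overlap ``1 - jitter`` on the appropriate
    haplotype's annotation, with recent, low divergences) and
    ``n_other_svs`` non-TE SVs whose midpoints follow a log-linear density
    ``exp(beta . z)`` in the standardized 50-kb flank feature densities
    (``effect_log_odds`` keyed by feature; all-zero means uniform).  A
    read-based callset re-detects a configurable fraction of the assembly
    SVs (het) and genotypes a small fraction hom-alt (planted
    mis-assemblies).
    """
    if layout is None:
        layout = default_layout()
    if len(layout.chroms) < 2:
        raise ValueError("layout needs >= 2 chromosomes")
    if not 0 <= boundary_jitter_frac < 0.25:
        raise ValueError("boundary_jitter_frac must be in [0, 0.25)")
    betas = dict(effect_log_odds or {})
    unknown = set(betas) - {"te", "tandem", "line", "gene"}
    if unknown:
        raise ValueError(f"unknown effect features: {sorted(unknown)}")

    f_rng = _rng(seed, "features")
    repeats_hap1 = _background_repeats(f_rng, layout, 0.22, "hap1")
    repeats_hap2 = _background_repeats(f_rng, layout, 0.22, "hap2")
    tandem = []
    for chrom, clen in layout.chrom_lengths.items():
        n = int(0.045 * clen / 1_200)
        lengths = _draw_lengths(f_rng, n, math.log(1_000), 0.7, 100, 6_000)
        starts = f_rng.integers(0, clen - lengths)
        tandem.extend(
            GenomicInterval(chrom, int(s), int(s + L)) for s, L in zip(starts, lengths)
        )
    genes = _background_genes(f_rng, layout)
    features = {
        "te": [h.interval for h in repeats_hap1],
        "tandem": tandem,
        "line": [h.interval for h in repeats_hap1 if h.class_label == "LINE"],
        "gene": [g.interval for g in genes],
    }

    # --- planted heterozygous TE insertions -------------------------------
    te_rng = _rng(seed, "het_te")
    svs: list[SVRecord] = []
    truth_te = []
    classes = list(_HET_CLASS_P)
    cls_p = np.array([_HET_CLASS_P[c] for c in classes])
    chroms = layout.chroms
    clens = np.array([layout.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_p = clens / clens.sum()
    te_gap_index = CoverageIndex(layout.gaps)
    for i in range(n_te_insertions):
        L = int(_draw_lengths(te_rng, 1, math.log(1_200), 0.7, 300, 8_000)[0])
        while True:
            chrom = chroms[int(te_rng.choice(len(chroms), p=chrom_p))]
            p = int(te_rng.integers(0, layout.chrom_lengths[chrom] - L))
            if te_gap_index.covered_bp(chrom, p, p + L) == 0:
                break
        sv_type = "DEL" if i % 2 == 0 else "INS"
        if sv_type == "DEL":
            sv = SVRecord("DEL", GenomicInterval(chrom, p, p + L), L, "het")
        else:
            sv = SVRecord("INS", GenomicInterval(chrom, p, p + 1), L, "het")
        # matching repeat copy, shifted by the boundary jitter
        d = int(round(boundary_jitter_frac * te_rng.random() * L))
        if te_rng.random() < 0.5:
            d = -d
        hs = max(0, min(p + d, layout.chrom_lengths[chrom] - L))
        label = classes[int(te_rng.choice(len(classes), p=cls_p))]
        fam = {"LINE": "L2-1", "LTR": "Gypsy-1", "DNA": "hAT-1", "other": "Unknown-1"}[label]
        hit = RepeatHit(
            interval=GenomicInterval(chrom, hs, hs + L),
            family=fam,
            class_label=label,
            divergence_pct=float(te_rng.exponential(0.5)),  # recent insertions
            score=float(te_rng.integers(500, 3_000)),
        )
        if sv_type == "DEL":
            repeats_hap1.append(hit)
        else:
            repeats_hap2.append(hit)
        svs.append(sv)
        truth_te.append((chrom, sv.ref_interval.start, sv_type, label))

    # --- non-TE SVs placed by the log-linear density ----------------------
    sv_rng = _rng(seed, "other_sv")
    indices = {name: CoverageIndex(ivs) for name, ivs in features.items()}

    def flank_density(chrom_arr, mids):
        out = np.zeros((len(mids), len(betas)), dtype=float)
        names = list(betas)
        for chrom in set(chrom_arr):
            m = chrom_arr == chrom
            clen = layout.chrom_lengths[chrom]
            lo = np.maximum(0, mids[m] - flank_bp)
            hi = np.minimum(clen, mids[m] + flank_bp)
            for j, name in enumerate(names):
                out[np.flatnonzero(m), j] = indices[name].covered_bp(chrom, lo, hi) / np.maximum(
                    1, hi - lo
                )
        return out

    beta_vec = np.array([betas[k] for k in betas], dtype=float)
    # calibration sample fixes the standardization (the uniform background scale)
    calib_n = 5_000
    calib_chrom = np.array(chroms)[sv_rng.choice(len(chroms), size=calib_n, p=chrom_p)]
    calib_pos = (sv_rng.random(calib_n) * (clens[[chroms.index(c) for c in calib_chrom]] - 1)).astype(int)
    mu = sig = None
    accept_est = 1.0
    if betas:
        dens = flank_density(calib_chrom, calib_pos)
        mu = dens.mean(axis=0)
        sig = dens.std(axis=0, ddof=1)
        sig[sig == 0] = 1.0
        z_calib = (dens - mu) / sig @ beta_vec
        zmax = z_calib.max() + 0.5
        accept_est = max(1e-4, float(np.mean(np.exp(z_calib - zmax))))

    all_repeats = repeats_hap1 + repeats_hap2
    rep_index = {}
    for h in all_repeats:
        rep_index.setdefault(h.interval.chrom, []).append(h)

    def te_collision(span: GenomicInterval) -> bool:
        for h in rep_index.get(span.chrom, []):
            if passes_reciprocal(span, h.interval):
                return True
        return False

    gap_index = CoverageIndex(layout.gaps)
    other_types = ["DEL", "INS", "INV", "DUP", "TRA"]
    type_p = np.array([0.25, 0.25, 0.2, 0.2, 0.1])
    placed = 0
    truth_other = []
    guard = 0
    while placed < n_other_svs:
        guard += 1
        if guard > 2_000:
            raise PlacementError("could not place non-TE SVs (density too restrictive)")
        batch = int(np.clip(1.5 * (n_other_svs - placed) / accept_est, 1_000, 200_000))
        bc = np.array(chroms)[sv_rng.choice(len(chroms), size=batch, p=chrom_p)]
        bl = _draw_lengths(sv_rng, batch, math.log(2_000), 1.0, 100, 60_000)
        bstart = (sv_rng.random(batch) * (clens[[chroms.index(c) for c in bc]] - bl)).astype(int)
        mids = bstart + bl // 2
        if betas:
            z = ((flank_density(bc, mids) - mu) / sig) @ beta_vec
            accept = sv_rng.random(batch) < np.exp(z - zmax)
        else:
            accept = np.ones(batch, dtype=bool)
        for i in np.flatnonzero(accept):
            if placed >= n_other_svs:
                break
            chrom, L, s = str(bc[i]), int(bl[i]), int(bstart[i])
            # SVs are never called inside assembly gaps; keeping planted SVs
            # out of gaps also matches the gap-excluded shuffled controls
            if gap_index.covered_bp(chrom, s, s + L) > 0:
                continue
            sv_type = other_types[int(sv_rng.choice(len(other_types), p=type_p))]
            if sv_type == "INS":
                sv = SVRecord("INS", GenomicInterval(chrom, s, s + 1), L, "het")
            else:
                sv = SVRecord(sv_type, GenomicInterval(chrom, s, s + L), L, "het")
            if sv_type in ("INS", "DEL") and te_collision(sv.span()):
                continue  # keep non-TE indels clean of reciprocal TE matches
            svs.append(sv)
            truth_other.append((chrom, s, sv_type))
            placed += 1

    # --- read-based callset -----------------------------------------------
    r_rng = _rng(seed, "reads")
    p_het, p_hom = read_support
    read_svs = []
    truth_support = []
    for sv in svs:
        u = r_rng.random()
        if u < p_het:
            gt, lab = "het", "het_supported"
        elif u < p_het + p_hom:
            gt, lab = "hom_alt", "hom_alt"
        else:
            truth_support.append("unsupported")
            continue
        shift = int(r_rng.integers(-200, 201))
        s = max(0, sv.ref_interval.start + shift)
        e = max(s + 1, sv.ref_interval.end + shift)
        if e > layout.chrom_lengths[sv.ref_interval.chrom]:
            e = layout.chrom_lengths[sv.ref_interval.chrom]
            s = min(s, e - 1)
        read_svs.append(
            SVRecord(
                sv.sv_type,
                GenomicInterval(sv.ref_interval.chrom, s, e),
                max(1, int(sv.length_bp * (1 + 0.1 * r_rng.standard_normal()))),
                gt,
                source="reads",
            )
        )
        truth_support.append(lab)

    truth = {
        "seed": seed,
        "n_te_insertions": n_te_insertions,
        "n_other_svs": n_other_svs,
        "boundary_jitter_frac": boundary_jitter_frac,
        "effect_log_odds": betas,
        "planted_te": truth_te,
        "planted_other": truth_other,
        "read_support_labels": truth_support,
    }
    return DiploidSVDataset(
        layout=layout,
        svs=svs,
        read_svs=read_svs,
        repeats_hap1=repeats_hap1,
        repeats_hap2=repeats_hap2,
        genes=genes,
        features=features,
        truth=truth,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# branch mutations


@dataclass
class BranchMutationSim:
    mutations: list[BranchMutation]
    repeats: list[RepeatHit]
    truth: dict
    seed: int


def simulate_branch_mutations(
    tree: DatedTree,
    ins_rate_bp_per_my: float | Mapping[str, float] = 300_000.0,
    del_rate_bp_per_my: float | Mapping[str, float] = 50_000.0,
    te_fraction: float = 0.6,
    layout: GenomeLayout | None = None,
    mean_event_bp: int = 1_000,
    n_decoy_repeats: int = 200,
    seed: int = 0,
) -> BranchMutationSim:
    """Branch-mutation tables under per-branch insertion/deletion rates.

    Insertion events arrive as a Poisson process with expectation
    ``rate x duration`` bp per branch; a ``te_fraction`` of events carry a
    matching repeat copy spanning exactly their merged lifted interval.
    Each lifted insertion is fragmented into up to 3 pieces separated by
    gaps < 100 bp sharing one ancestral event id, to exercise the
    lift-merge rule.  Lifted intervals are packed disjointly (200 bp
    spacing) so reciprocal-overlap attribution is exact by construction.
    """
    rng = _rng(seed, "branch")

    def rate(r, bid):
        return float(r[bid]) if isinstance(r, Mapping) else float(r)

    if layout is None:
        # size the reference to the expected event load (fragment gaps plus
        # inter-event spacing add ~50% overhead) with 2x headroom
        expected_bp = sum(
            rate(ins_rate_bp_per_my, bid) * dur for bid, dur in tree.durations.items()
        )
        expected_bp += n_decoy_repeats * 1_650
        chrom_len = max(1_000_000, int(3.0 * expected_bp / 20))
        layout = default_layout(n_chroms=20, chrom_len=chrom_len, with_gaps=False)

    cursors = {c: 0 for c in layout.chroms}
    chrom_cycle = list(layout.chroms)

    def alloc(total: int) -> GenomicInterval:
        c0 = chrom_cycle[int(rng.integers(len(chrom_cycle)))]
        candidates = [c0, *(c for c in chrom_cycle if c != c0)]
        for c in candidates:
            if cursors[c] + total <= layout.chrom_lengths[c]:
                s = cursors[c]
                cursors[c] = s + total + 200
                return GenomicInterval(c, s, s + total)
        raise PlacementError("reference layout exhausted; enlarge it or lower rates")

    mutations: list[BranchMutation] = []
    repeats: list[RepeatHit] = []
    per_branch = {}
    classes = ["DNA", "LINE", "LTR"]
    cls_p = np.array([0.40, 0.42, 0.18])
    ev = 0
    for bid, dur in tree.durations.items():
        ins_total = 0
        del_total = 0
        n_te = 0
        n_nonte = 0
        comp = {c: 0 for c in classes}
        lam_ins = rate(ins_rate_bp_per_my, bid) * dur / mean_event_bp
        lam_del = rate(del_rate_bp_per_my, bid) * dur / mean_event_bp
        for _ in range(int(rng.poisson(lam_ins))):
            size = int(rng.integers(int(0.5 * mean_event_bp), int(1.5 * mean_event_bp) + 1))
            is_te = rng.random() < te_fraction
            ev += 1
            event_id = f"{bid}:e{ev}"
            n_frag = int(rng.integers(1, 4))
            gaps = rng.integers(10, 100, size=max(0, n_frag - 1))
            span = alloc(size + int(gaps.sum()))
            # fragment sizes: split `size` into n_frag positive pieces
            if n_frag == 1:
                pieces = [size]
            else:
                cuts = np.sort(rng.choice(np.arange(1, size), size=n_frag - 1, replace=False))
                pieces = np.diff([0, *cuts.tolist(), size]).tolist()
            pos = span.start
            for pi, piece in enumerate(pieces):
                mutations.append(
                    BranchMutation(
                        branch_id=bid,
                        kind="insertion",
                        bp=int(piece),
                        lifted_interval=GenomicInterval(span.chrom, pos, pos + int(piece)),
                        event_id=event_id,
                    )
                )
                pos += int(piece)
                if pi < len(gaps):
                    pos += int(gaps[pi])
            ins_total += size
            if is_te:
                n_te += 1
                label = classes[int(rng.choice(len(classes), p=cls_p))]
                comp[label] += 1
                repeats.append(
                    RepeatHit(
                        interval=span,
                        family=f"{label}-fam",
                        class_label=label,
                        divergence_pct=float(rng.gamma(2.0, 1.0)),
                        score=float(rng.integers(300, 3_000)),
                    )
                )
            else:
                n_nonte += 1
        for _ in range(int(rng.poisson(lam_del))):
            size = int(rng.integers(int(0.5 * mean_event_bp), int(1.5 * mean_event_bp) + 1))
            mutations.append(BranchMutation(branch_id=bid, kind="deletion", bp=size))
            del_total += size
        per_branch[bid] = {
            "ins_bp": ins_total,
            "del_bp": del_total,
            "n_te_events": n_te,
            "n_nonte_events": n_nonte,
            "n_events": n_te + n_nonte,
            "class_counts": comp,
            "duration_my": dur,
        }
    # decoy repeat copies in untouched territory (never near planted events)
    for _ in range(n_decoy_repeats):
        size = int(rng.integers(300, 3_000))
        try:
            span = alloc(size)
        except PlacementError:
            break
        label = classes[int(rng.integers(len(classes)))]
        repeats.append(
            RepeatHit(
                interval=span,
                family=f"{label}-decoy",
                class_label=label,
                divergence_pct=float(rng.gamma(5.0, 1.5)),
                score=float(rng.integers(300, 3_000)),
            )
        )
    truth = {"seed": seed, "te_fraction": te_fraction, "per_branch": per_branch}
    return BranchMutationSim(mutations=mutations, repeats=repeats, truth=truth, seed=seed)


# ---------------------------------------------------------------------------
# depth tracks


def simulate_depth_tracks(
    ce_intervals: Sequence[GenomicInterval],
    ancestry_truth: Sequence[str],
    all_species: Sequence[str],
    focal_clade: Sequence[str],
    min_cov: float = 0.75,
    margin: float = 0.05,
    seed: int = 0,
) -> dict[str, DepthTrack]:
    """Per-species alignment-presence tracks realizing a planted ancestry.

    For each element and species a covered sub-interval is drawn so the
    planted label holds: ``ancestral`` elements are covered at or above
    ``min_cov`` by every species, ``clade_specific`` only by the focal
    clade, and ``other`` falls below threshold for at least one clade
    member.  ``margin`` sets how far coverages stay from the 75% boundary
    (0 places positives exactly on the inclusive boundary).
    """
    if len(ancestry_truth) != len(ce_intervals):
        raise ValueError("ancestry_truth must parallel ce_intervals")
    bad = set(ancestry_truth) - {"ancestral", "clade_specific", "other"}
    if bad:
        raise ValueError(f"unknown ancestry labels: {sorted(bad)}")
    focal = list(focal_clade)
    nonfocal = [s for s in all_species if s not in set(focal)]
    if not nonfocal:
        raise ValueError("need at least one non-clade species")
    rng = _rng(seed, "depth")
    covered: dict[str, list[GenomicInterval]] = {sp: [] for sp in all_species}

    def add(sp: str, iv: GenomicInterval, high: bool):
        L = iv.length
        lo_bp = math.ceil(min_cov * L)  # minimal bp satisfying >= min_cov (inclusive)
        if high:
            floor_bp = min(L, max(lo_bp, math.ceil((min_cov + margin) * L)))
            bp = int(rng.integers(floor_bp, L + 1))
        else:
            cap = min(lo_bp - 1, math.floor(max(0.0, min_cov - margin) * L))
            bp = int(rng.integers(0, max(0, cap) + 1))
        if bp <= 0:
            return
        off = int(rng.integers(0, L - bp + 1))
        covered[sp].append(GenomicInterval(iv.chrom, iv.start + off, iv.start + off + bp))

    for iv, label in zip(ce_intervals, ancestry_truth):
        if label == "ancestral":
            for sp in all_species:
                add(sp, iv, True)
        elif label == "clade_specific":
            for sp in focal:
                add(sp, iv, True)
            n_low = 1 + int(rng.integers(0, len(nonfocal)))
            lows = set(rng.choice(len(nonfocal), size=n_low, replace=False).tolist())
            for i, sp in enumerate(nonfocal):
                add(sp, iv, i not in lows)
        else:  # other: at least one focal member below threshold
            low_focal = int(rng.integers(0, len(focal)))
            for i, sp in enumerate(focal):
                add(sp, iv, i != low_focal)
            for sp in nonfocal:
                add(sp, iv, bool(rng.random() < 0.5))
    return {sp: DepthTrack(species=sp, intervals=tuple(ivs)) for sp, ivs in covered.items()}


# ---------------------------------------------------------------------------
# repeat divergences (landscape input)


def simulate_repeat_divergences(
    n: int = 5_000,
    age_components: Sequence[tuple[float, float, float]] = ((2.0, 0.5, 0.5), (9.0, 1.0, 0.5)),
    rate: float = 3.2e-3,
    divisor_mode: str = "2r",
    layout: GenomeLayout | None = None,
    seed: int = 0,
) -> tuple[list[RepeatHit], dict]:
    """Repeat copies whose divergences encode a planted activity history.

    Ages are drawn from a Gaussian mixture (``(mean MY, sd, weight)``
    components, truncated at 0) and converted to divergence by inverting
    the dating formula: ``K = age x divisor x 100`` with divisor ``r`` or
    ``2r``.  The default components plant the bimodal burst structure
    (recent ~2 MY and older ~9 MY peaks) that landscape binning must
    recover.
    """
    if layout is None:
        layout = default_layout(with_gaps=False)
    rng = _rng(seed, "landscape")
    comps = list(age_components)
    w = np.array([c[2] for c in comps], dtype=float)
    w = w / w.sum()
    which = rng.choice(len(comps), size=n, p=w)
    ages = np.array([max(0.0, rng.normal(comps[i][0], comps[i][1])) for i in which])
    divisor = rate if divisor_mode == "r" else 2 * rate
    K = ages * divisor * 100.0
    lengths = _draw_lengths(rng, n, math.log(800), 0.7, 200, 5_000)
    classes = ["DNA", "LINE", "LTR"]
    hits = []
    chroms = layout.chroms
    cursors = {c: 0 for c in chroms}
    for i in range(n):
        c = chroms[i % len(chroms)]
        L = int(lengths[i])
        if cursors[c] + L > layout.chrom_lengths[c]:
            raise PlacementError("layout too small for requested repeat count")
        s = cursors[c]
        cursors[c] = s + L + 10
        label = classes[i % 3]
        hits.append(
            RepeatHit(
                interval=GenomicInterval(c, s, s + L),
                family=f"{label}-sim",
                class_label=label,
                divergence_pct=float(K[i]),
                score=float(rng.integers(300, 3_000)),
            )
        )
    truth = {
        "seed": seed,
        "age_components": comps,
        "rate": rate,
        "divisor_mode": divisor_mode,
        "component_assignment": which.tolist(),
    }
    return hits, truth


# ---------------------------------------------------------------------------
# afgp locus


_CODON = {"A": "GCT", "T": "ACT", "L": "CTT", "F": "TTT", "R": "CGT", "G": "GGT",
          "P": "CCT", "Q": "CAA", "S": "TCT", "V": "GTT", "M": "ATG", "K": "AAA"}


def _dna(protein: str) -> str:
    return "".join(_CODON[a] for a in protein)


def _exon2(n_repeats: int, spacer_every: int = 10) -> str:
    """Exon-2 DNA: (Thr-Ala-Ala)^n polyprotein with ALF spacers, AARG end."""
    prot = []
    for i in range(n_repeats):
        prot.append("TAA")  # Thr-Ala-Ala tripeptide repeat
        if (i + 1) % spacer_every == 0 and i + 1 < n_repeats:
            prot.append("ALF")  # matches the X-wildcard spacer motif XLF
    prot.append("AARG")
    return _dna("".join(prot))


@dataclass
class AfgpLocusSim:
    genes: list[AfgpGeneModel]
    layout: LocusLayout
    truth: dict


def simulate_afgp_locus(
    n_units: int = 3,
    te_motif: Sequence[str] = ("L2-1", "hAT-3"),
    pseudogene_events: Mapping[str, str] | None = None,
    n_chimeric: int = 1,
    chrom: str = "chr16",
    seed: int = 0,
) -> AfgpLocusSim:
    """A token-level afgp locus built from tandem duplication units.

    Each unit holds two pairs of afgp genes with alternating orientation
    (+ - + -) followed by the TE motif, so the locus token sequence is the
    unit repeated ``n_units`` times, flanked by the hsl / tomm40 anchor
    genes (plus optional chimeric afgp/tlp copies).  ``pseudogene_events``
    maps gene ids to one of ``drop_exon1``, ``frameshift``,
    ``strip_terminal``, ``delete_tlp_exons``.
    """
    events = dict(pseudogene_events or {})
    rng = _rng(seed, "afgp")
    exon1 = _dna("M" + "LF" * 9 + "K")  # 20-aa signal peptide stand-in
    genes: list[AfgpGeneModel] = []
    tokens: list[LocusToken] = []
    pos = 10_000
    spacing = 500

    def add_token(tok_kind, name, length, strand=None, gene_type=None):
        nonlocal pos
        iv = GenomicInterval(chrom, pos, pos + length)
        pos += length + spacing
        tokens.append(LocusToken(kind=tok_kind, name=name, strand=strand, interval=iv, gene_type=gene_type))
        return iv

    def make_gene(gid, strand, gene_type="afgp", n_tlp=0):
        n_rep = int(rng.integers(30, 60))
        g = AfgpGeneModel(
            gene_id=gid,
            strand=strand,
            gene_type=gene_type,
            exon1_seq=exon1,
            exon2_seq=_exon2(n_rep),
            tlp_exon_seqs=tuple(_dna("VQPS" * 12) for _ in range(n_tlp)),
        )
        g = _apply_event(g, events.get(gid))
        iv = add_token("gene", gid, len(g.exon2_seq or "") + len(exon1) + 200, strand, gene_type)
        return AfgpGeneModel(
            gene_id=g.gene_id, strand=g.strand, gene_type=g.gene_type,
            exon1_seq=g.exon1_seq, exon2_seq=g.exon2_seq,
            tlp_exon_seqs=g.tlp_exon_seqs, interval=iv,
        )

    add_token("gene", "hsl", 8_000, "+", "other")
    for c in range(n_chimeric):
        genes.append(make_gene(f"afgp_tlp{c + 1}", "+", "afgp_tlp", n_tlp=3))
    gi = 0
    for _u in range(n_units):
        for strand in ("+", "-", "+", "-"):
            gi += 1
            genes.append(make_gene(f"afgp{gi}", strand))
        for fam in te_motif:
            add_token("repeat", fam, int(rng.integers(800, 2_500)))
    add_token("gene", "tomm40", 6_000, "+", "other")
    truth = {
        "seed": seed,
        "n_units": n_units,
        "n_afgp_genes": gi,
        "unit_tokens": 4 + len(te_motif),
        "pseudogene_events": events,
        "pseudogenes": sorted(events),
    }
    return AfgpLocusSim(genes=genes, layout=LocusLayout(tokens=tuple(tokens)), truth=truth)


def _apply_event(g: AfgpGeneModel, event: str | None) -> AfgpGeneModel:
    if event is None:
        return g
    kw = dict(
        gene_id=g.gene_id, strand=g.strand, gene_type=g.gene_type,
        exon1_seq=g.exon1_seq, exon2_seq=g.exon2_seq, tlp_exon_seqs=g.tlp_exon_seqs,
    )
    if event == "drop_exon1":
        kw["exon1_seq"] = None
    elif event == "frameshift":
        kw["exon2_seq"] = g.exon2_seq[:100] + g.exon2_seq[101:]  # 1-bp deletion
    elif event == "strip_terminal":
        # replace the AARG-coding tail with an unrelated in-frame tail
        kw["exon2_seq"] = g.exon2_seq[:-12] + _dna("VQPS")
    elif event == "delete_tlp_exons":
        if g.gene_type != "afgp_tlp":
            raise ValueError(f"{g.gene_id}: delete_tlp_exons applies to chimeric genes only")
        kw["tlp_exon_seqs"] = ()
    else:
        raise ValueError(f"unknown pseudogene event {event!r}")
    return AfgpGeneModel(**kw)


# ---------------------------------------------------------------------------
# gene trees


@dataclass
class GeneTreeSim:
    trees: list[tuple[str, str]]  # (tree id, newick)
    truth: dict  # tree id -> {"keep": bool, "mode": str}


def _random_clade_newick(rng, taxa: list[str]) -> str:
    if len(taxa) == 1:
        return f"{taxa[0]}:1"
    k = int(rng.integers(1, len(taxa)))
    idx = rng.permutation(len(taxa))
    left = [taxa[i] for i in idx[:k]]
    right = [taxa[i] for i in idx[k:]]
    return f"({_random_clade_newick(rng, left)},{_random_clade_newick(rng, right)}):1"


def simulate_gene_trees(
    n: int,
    clade_taxa: Sequence[str],
    sister_taxon: str,
    outgroup_taxa: Sequence[str],
    p_monophyletic: float = 0.6,
    seed: int = 0,
) -> GeneTreeSim:
    """Gene trees with planted keep/discard truth for the monophyly filter.

    A kept tree nests the focal clade as a monophyletic group sister to
    ``sister_taxon``; discarded trees either break clade monophyly (one
    clade member swapped outside) or keep the clade but interpose an
    outgroup between it and the sister species.
    """
    if len(outgroup_taxa) < 2:
        raise ValueError("need >= 2 outgroup taxa to build violations")
    rng = _rng(seed, "trees")
    trees = []
    truth = {}
    for i in range(n):
        tid = f"og{i + 1:04d}"
        keep = bool(rng.random() < p_monophyletic)
        clade = list(clade_taxa)
        outs = list(outgroup_taxa)
        mode = "monophyletic_sister"
        if keep:
            core = f"({_random_clade_newick(rng, clade)},{sister_taxon}:1):1"
        else:
            if rng.random() < 0.5 and len(clade) >= 2:
                mode = "clade_broken"
                j = int(rng.integers(len(clade)))
                k = int(rng.integers(len(outs)))
                clade[j], outs[k] = outs[k], clade[j]
                core = f"({_random_clade_newick(rng, clade)},{sister_taxon}:1):1"
            else:
                mode = "sister_displaced"
                k = int(rng.integers(len(outs)))
                interloper = outs.pop(k)
                core = f"(({_random_clade_newick(rng, clade)},{interloper}:1):1,{sister_taxon}:1):1"
        rest = "".join(f",{t}:1" for t in outs)
        newick = f"({core}{rest});"
        trees.append((tid, newick))
        truth[tid] = {"keep": keep, "mode": mode}
    return GeneTreeSim(trees=trees, truth=truth)


def dump_truth(truth: dict, path: str | Path) -> None:
    """Serialize a truth dict next to its generated files."""
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True))
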