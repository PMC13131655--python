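"""Haplotype-comparison quantifications for a phased diploid assembly.

Stage 1 of the pipeline: hemizygous genome fraction, heterozygous-TE
insertion calling at reciprocal overlap, genomic context of insertions,
assembly-vs-read SV callset concordance (mis-assembly flagging), the
mixed-model association between SV occurrence and local genomic features
against shuffled controls, and the divergence shift test for recent TE
activity.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import (
    CoverageIndex,
    GenomeLayout,
    GenomicInterval,
    distance_to_chrom_end,
    distance_to_nearest,
    reciprocal_overlap,
    shuffle_intervals,
)
from .io import GeneModel, RepeatHit, SVRecord
from .stats import RankSumResult, rank_sum_test

__all__ = [
    "HetTEMatch",
    "SVSupportSummary",
    "AssociationFit",
    "hemizygous_fraction",
    "detect_het_te_insertions",
    "insertion_context",
    "compare_sv_callsets",
    "sv_feature_association",
    "divergence_shift_test",
]

CONTEXT_LABELS = ("exon", "intron", "flank", "intergenic")


def hemizygous_fraction(svs: Sequence[SVRecord], genome_bp: int) -> float:
    """Fraction of the genome in a hemizygous state.

    The union (not the sum, to avoid double counting) of the footprints of
    heterozygous insertions and deletions divided by the genome size;
    insertion footprints are the anchor-projected inserted length.
    """
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    spans = [
        sv.span()
        for sv in svs
        if sv.genotype == "het" and sv.sv_type in ("INS", "DEL")
    ]
    if not spans:
        return 0.0
    index = CoverageIndex(spans)
    covered = sum(
        int(index.covered_bp(c, 0, np.iinfo(np.int64).max // 2))
        for c in {s.chrom for s in spans}
    )
    return covered / genome_bp


@dataclass(frozen=True)
class HetTEMatch:
    """One heterozygous SV paired with its best-overlapping repeat copy."""

    sv: SVRecord
    hit: RepeatHit
    frac_sv: float
    frac_hit: float


def detect_het_te_insertions(
    indel_svs: Sequence[SVRecord],
    repeats_del: Sequence[RepeatHit],
    repeats_ins: Sequence[RepeatHit] | None = None,
    min_reciprocal: float = 0.75,
) -> list[HetTEMatch]:
    """Call heterozygous TE insertions by reciprocal overlap with repeats.

    Deletions (sequence present on Hap1, absent on Hap2) are intersected
    with the Hap1 repeat annotation (``repeats_del``); insertions with the
    Hap2 annotation (``repeats_ins``, defaulting to ``repeats_del`` when a
    single merged table is supplied).  A pair is reported iff *both*
    reciprocal fractions reach ``min_reciprocal`` (inclusive); an SV
    matching several repeat copies keeps the one with the most overlapping
    bases (ties: earlier start).
    """
    if repeats_ins is None:
        repeats_ins = repeats_del
    tables = {"DEL": _chrom_arrays(repeats_del), "INS": _chrom_arrays(repeats_ins)}
    matches: list[HetTEMatch] = []
    for sv in indel_svs:
        if sv.genotype != "het" or sv.sv_type not in ("INS", "DEL"):
            continue
        span = sv.span()
        starts, ends, hits = tables[sv.sv_type].get(span.chrom, (None, None, None))
        if starts is None:
            continue
        sel = np.flatnonzero((starts < span.end) & (ends > span.start))
        best = None
        for j in sel:
            fa, fb = reciprocal_overlap(span, hits[j].interval)
            if fa >= min_reciprocal and fb >= min_reciprocal:
                ov = span.overlap_bp(hits[j].interval)
                key = (-ov, hits[j].interval.start)
                if best is None or key < best[0]:
                    best = (key, HetTEMatch(sv, hits[j], fa, fb))
        if best is not None:
            matches.append(best[1])
    return matches


def _chrom_arrays(hits: Sequence[RepeatHit]):
    out: dict[str, tuple[np.ndarray, np.ndarray, list[RepeatHit]]] = {}
    per: dict[str, list[RepeatHit]] = {}
    for h in hits:
        per.setdefault(h.interval.chrom, []).append(h)
    for chrom, items in per.items():
        items.sort(key=lambda h: h.interval.start)
        out[chrom] = (
            np.array([h.interval.start for h in items], dtype=np.int64),
            np.array([h.interval.end for h in items], dtype=np.int64),
            items,
        )
    return out


def insertion_context(
    insertions: Sequence[SVRecord] | Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    flank_bp: int = 2500,
) -> tuple[list[str], dict[str, int]]:
    """Label each insertion site as exon / intron / flank / intergenic.

    Priority is exon > intron > flank > intergenic, decided at the
    reference-side footprint of the variant.  Returns per-insertion labels
    plus a count table; counts always sum to the number of insertions.
    """
    exon_idx = CoverageIndex([e for g in genes for e in g.exons])
    gene_idx = CoverageIndex([g.interval for g in genes])
    flank_idx = CoverageIndex(
        [
            GenomicInterval(
                g.interval.chrom,
                max(0, g.interval.start - flank_bp),
                g.interval.end + flank_bp,
            )
            for g in genes
        ]
    )
    labels = []
    for item in insertions:
        iv = item.ref_interval if isinstance(item, SVRecord) else item
        if exon_idx.covered_bp(iv.chrom, iv.start, iv.end) > 0:
            labels.append("exon")
        elif gene_idx.covered_bp(iv.chrom, iv.start, iv.end) > 0:
            labels.append("intron")
        elif flank_idx.covered_bp(iv.chrom, iv.start, iv.end) > 0:
            labels.append("flank")
        else:
            labels.append("intergenic")
    counts = {lab: labels.count(lab) for lab in CONTEXT_LABELS}
    return labels, counts


@dataclass(frozen=True)
class SVSupportSummary:
    """Partition of assembly SVs by read-based support.

    ``het_supported``: confirmed heterozygous by reads; ``hom_alt``:
    genotyped homozygous-alternate by reads (putative mis-assembly);
    ``unsupported``: no matching read call.
    """

    labels: tuple[str, ...]
    percentages: dict[str, float]
    n_assembly: int
    n_read: int


def compare_sv_callsets(
    assembly_svs: Sequence[SVRecord],
    read_svs: Sequence[SVRecord],
    max_dist: int = 1000,
    min_size: int = 50,
    min_len_ratio: float = 0.7,
) -> SVSupportSummary:
    """Classify assembly SVs by concordance with a read-based callset.

    Both callsets are restricted to variants strictly larger than
    ``min_size`` bp.  An assembly SV matches a read SV iff same type, same
    chromosome, breakpoint distance <= ``max_dist`` and length ratio
    >= ``min_len_ratio``; matching is greedy one-to-one by breakpoint
    distance.
    """
    asm = [sv for sv in assembly_svs if sv.length_bp > min_size]
    rd = [sv for sv in read_svs if sv.length_bp > min_size]
    pairs = []
    for i, a in enumerate(asm):
        for j, r in enumerate(rd):
            if a.sv_type != r.sv_type or a.ref_interval.chrom != r.ref_interval.chrom:
                continue
            dist = abs(a.ref_interval.start - r.ref_interval.start)
            ratio = min(a.length_bp, r.length_bp) / max(a.length_bp, r.length_bp)
            if dist <= max_dist and ratio >= min_len_ratio:
                pairs.append((dist, i, j))
    pairs.sort()
    matched_a: dict[int, int] = {}
    used_r: set[int] = set()
    for dist, i, j in pairs:
        if i in matched_a or j in used_r:
            continue
        matched_a[i] = j
        used_r.add(j)
    labels = []
    for i, a in enumerate(asm):
        if i not in matched_a:
            labels.append("unsupported")
        elif rd[matched_a[i]].genotype == "hom_alt":
            labels.append("hom_alt")
        else:
            labels.append("het_supported")
    n = len(labels)
    pct = {
        lab: (100.0 * labels.count(lab) / n if n else 0.0)
        for lab in ("het_supported", "hom_alt", "unsupported")
    }
    return SVSupportSummary(tuple(labels), pct, len(asm), len(rd))


@dataclass
class AssociationFit:
    """Mixed-logistic fit of SV occurrence against local genomic features.

    One row per predictor: coefficient on the standardized scale, standard
    error, odds ratio and Wald 95% CI (``exp(coef +/- 1.96*SE)``).
    """

    table: pd.DataFrame
    random_intercept_sd: float
    n_cases: int
    n_controls: int
    method: str
    converged: bool
    seed: int | None = None


def sv_feature_association(
    svs: Sequence[SVRecord],
    layout: GenomeLayout,
    features: Mapping[str, Sequence[GenomicInterval]],
    flank_bp: int = 50_000,
    seed: int | None = None,
    include_length: bool = True,
    ci_z: float = 1.96,
) -> AssociationFit:
    """Fit SV occurrence (observed = 1) vs shuffled controls (0).

    Controls are an equal number of length-preserved randomized intervals
    (gap-excluded).  Predictors: distance to the nearest chromosome end,
    distance to the closest assembly gap (only when the layout has gaps),
    SV length, and the proportion of bases annotated as each feature within
    ``flank_bp`` windows around the breakpoint midpoint.  All predictors
    are standardized to the control sample's mean and SD, so coefficients
    are log-odds per SD of the genomic background.  The model is a logistic
    regression with a chromosome-level random intercept fitted by
    variational Bayes; on failure it falls back to fixed chromosome
    effects, flagged in ``method``.
    """
    if seed is None:
        raise ValueError("seed is mandatory (controls are randomized)")
    if len(layout.chroms) < 2:
        raise ValueError("association requires >= 2 chromosomes")
    case_ivs = [sv.ref_interval for sv in svs]
    rng = np.random.default_rng(seed)
    control_ivs = shuffle_intervals(case_ivs, layout, rng, exclude_gaps=True)
    indices = {name: CoverageIndex(ivs) for name, ivs in features.items()}
    gap_list = list(layout.gaps)

    def predictors(ivs: list[GenomicInterval]) -> pd.DataFrame:
        rows = {}
        rows["dist_chrom_end"] = [distance_to_chrom_end(iv, layout) for iv in ivs]
        if gap_list:
            rows["dist_gap"] = [
                d if (d := distance_to_nearest(iv, gap_list)) is not None else layout.chrom_lengths[iv.chrom]
                for iv in ivs
            ]
        if include_length:
            rows["length"] = [iv.length for iv in ivs]
        mids = np.array([iv.midpoint() for iv in ivs])
        chroms = [iv.chrom for iv in ivs]
        for name, idx in indices.items():
            vals = np.empty(len(ivs))
            for chrom in set(chroms):
                m = np.array([c == chrom for c in chroms])
                clen = layout.chrom_lengths[chrom]
                lo = np.maximum(0, mids[m] - flank_bp)
                hi = np.minimum(clen, mids[m] + flank_bp)
                vals[m] = idx.covered_bp(chrom, lo, hi) / np.maximum(1, hi - lo)
            rows[f"{name}_frac"] = vals
        df = pd.DataFrame(rows)
        df["chrom"] = chroms
        return df

    cases = predictors(case_ivs)
    controls = predictors(control_ivs)
    pred_cols = [c for c in cases.columns if c != "chrom"]
    mu = controls[pred_cols].mean()
    sd = controls[pred_cols].std(ddof=1)
    degenerate = sd[sd == 0].index.tolist()
    if degenerate:
        # a constant predictor cannot be standardized; drop it rather than fit garbage
        pred_cols = [c for c in pred_cols if c not in degenerate]
    data = pd.concat([cases, controls], ignore_index=True)
    y = np.concatenate([np.ones(len(cases)), np.zeros(len(controls))])
    Z = (data[pred_cols] - mu[pred_cols]) / sd[pred_cols]
    for col in pred_cols:
        lo1, hi1 = Z[col][y == 1].min(), Z[col][y == 1].max()
        lo0, hi0 = Z[col][y == 0].min(), Z[col][y == 0].max()
        if hi1 < lo0 or hi0 < lo1:
            raise ValueError(f"perfect separation on predictor {col!r}")
    coef, se, re_sd, method, converged = _fit_mixed_logit(
        y, Z.to_numpy(), data["chrom"].to_numpy(), pred_cols
    )
    table = pd.DataFrame(
        {
            "predictor": pred_cols,
            "coef": coef,
            "se": se,
        }
    )
    table["odds_ratio"] = np.exp(table["coef"])
    table["ci_low"] = np.exp(table["coef"] - ci_z * table["se"])
    table["ci_high"] = np.exp(table["coef"] + ci_z * table["se"])
    return AssociationFit(
        table=table,
        random_intercept_sd=re_sd,
        n_cases=len(cases),
        n_controls=len(controls),
        method=method,
        converged=converged,
        seed=seed,
    )


def _fit_mixed_logit(y, X, chrom, names):
    """Chromosome random-intercept logistic fit; VB first, fixed-effect fallback."""
    import statsmodels.api as sm
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    chroms = sorted(set(chrom))
    exog = np.column_stack([np.ones(len(y)), X])
    vc = np.zeros((len(y), len(chroms)))
    for k, c in enumerate(chroms):
        vc[chrom == c, k] = 1.0
    try:
        model = BinomialBayesMixedGLM(
            y, exog, exog_vc=vc, ident=np.zeros(len(chroms), dtype=int),
            vcp_p=2.0, fe_p=2.0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # Laplace (MAP) fit: posterior SDs come from the full Hessian,
            # which stays calibrated under correlated predictors.  The
            # optimizer start point draws from the legacy global RNG, so pin
            # it for reproducible fits and restore the state afterwards.
            state = np.random.get_state()
            try:
                np.random.seed(1729)
                res = model.fit_map()
            finally:
                np.random.set_state(state)
        coef = res.fe_mean[1:]
        se = res.fe_sd[1:]
        re_sd = float(np.exp(res.vcp_mean[0]))
        return coef, se, re_sd, "laplace_mixed_logit", True
    except Exception:
        pass
    # fallback: fixed chromosome effects, flagged
    dummies = pd.get_dummies(pd.Categorical(chrom), drop_first=True).to_numpy(dtype=float)
    exog_f = np.column_stack([np.ones(len(y)), X, dummies])
    model = sm.Logit(y, exog_f)
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
    except Exception as exc:  # pragma: no cover - pathological inputs
        raise ValueError(f"logistic fit failed: {exc}") from exc
    k = X.shape[1]
    return res.params[1 : 1 + k], res.bse[1 : 1 + k], float("nan"), "fixed_chrom_logit", converged


def divergence_shift_test(
    het_te_divergences: Sequence[float],
    other_te_divergences: Sequence[float],
) -> RankSumResult:
    """One-sided rank-sum test: heterozygous-TE divergences shifted low.

    Heterozygous (recent) insertions are expected to be *less* diverged
    from their consensus than the rest of the annotation; the alternative
    is therefore "het sample stochastically smaller".
    """
    return rank_sum_test(het_te_divergences, other_te_divergences, alternative="less")
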