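"""Structural analytics for tandem antifreeze-glycoprotein (AFGP) loci.

An *afgp* gene is functional when it carries an exon-1 signal peptide and
an in-frame exon-2 polyprotein ending in the canonical AARG motif (with
the XLF spacer for chimeric afgp/tlp genes, which additionally need their
tlp-derived exons).  This module validates gene copies against those
structural rules, compares the locus between haplotypes (length allelic
variants with reading-frame logic), and detects the alternating-orientation
gene arrays and repeated gene+TE duplication units that characterize the
locus architecture.
"""

from __future__ import annotations

import difflib
import re
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .intervals import GenomicInterval

__all__ = [
    "AfgpGeneModel",
    "LocusToken",
    "LocusLayout",
    "ValidationResult",
    "LocusComparison",
    "AlternatingRun",
    "DuplicationMotif",
    "validate_gene",
    "compare_haplotype_loci",
    "detect_alternating_arrays",
    "detect_duplication_motif",
]

SPACER_MOTIF = "XLF"
TERMINAL_MOTIF = "AARG"

REASON_NO_SIGNAL = "missing exon-1 signal peptide"
REASON_FRAME = "exon-2 frame disrupted (frameshift or internal stop)"
REASON_NO_TERMINAL = f"missing {TERMINAL_MOTIF} terminal motif"
REASON_NO_SPACER = f"missing {SPACER_MOTIF} spacer"
REASON_NO_TLP = "tlp-derived exons deleted"


@dataclass(frozen=True)
class AfgpGeneModel:
    """One afgp (or chimeric afgp/tlp) gene copy.

    Either DNA exon sequences or precomputed boolean ``flags`` may be
    supplied; flags (keys ``has_exon1_signal``, ``exon2_frame_intact``,
    ``has_spacer_motif``, ``has_terminal_motif``, ``tlp_exons_present``)
    win when both are present.
    """

    gene_id: str
    strand: str = "+"
    gene_type: str = "afgp"  # "afgp" or "afgp_tlp" (chimeric)
    exon1_seq: str | None = None
    exon2_seq: str | None = None
    tlp_exon_seqs: tuple[str, ...] = ()
    flags: Mapping[str, bool] | None = None
    interval: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.gene_type not in ("afgp", "afgp_tlp"):
            raise ValueError(f"unknown gene type {self.gene_type!r}")
        if self.flags is None and self.exon1_seq is None and self.exon2_seq is None:
            raise ValueError(f"gene {self.gene_id}: empty model (no sequences, no flags)")

    @property
    def is_chimeric(self) -> bool:
        return self.gene_type == "afgp_tlp"


@dataclass(frozen=True)
class ValidationResult:
    gene_id: str
    status: str  # "functional" | "pseudogene"
    reasons: tuple[str, ...]
    checks: Mapping[str, bool]


def _translate(dna: str) -> str:
    """Translate truncating to whole codons; '*' marks stops."""
    usable = len(dna) - len(dna) % 3
    return str(Seq(dna[:usable]).translate())


def _motif_regex(motif: str) -> re.Pattern:
    # 'X' in a protein motif is a wildcard residue
    return re.compile("".join("." if c == "X" else re.escape(c) for c in motif))


def _checks(g: AfgpGeneModel, spacer: str, terminal: str) -> dict[str, bool]:
    if g.flags is not None:
        defaults = {
            "has_exon1_signal": True,
            "exon2_frame_intact": True,
            "has_spacer_motif": True,
            "has_terminal_motif": True,
            "tlp_exons_present": True,
        }
        defaults.update(g.flags)
        return defaults
    has_exon1 = bool(g.exon1_seq)
    frame_ok = False
    has_spacer = False
    has_terminal = False
    if g.exon2_seq:
        frame_ok = len(g.exon2_seq) % 3 == 0
        protein = _translate(g.exon2_seq)
        core = protein[:-1] if protein.endswith("*") else protein
        if "*" in core:
            frame_ok = False
        has_spacer = bool(_motif_regex(spacer).search(core))
        has_terminal = core.endswith(terminal)
    return {
        "has_exon1_signal": has_exon1,
        "exon2_frame_intact": frame_ok,
        "has_spacer_motif": has_spacer,
        "has_terminal_motif": has_terminal,
        "tlp_exons_present": len(g.tlp_exon_seqs) > 0,
    }


def validate_gene(
    g: AfgpGeneModel,
    spacer_motif: str = SPACER_MOTIF,
    terminal_motif: str = TERMINAL_MOTIF,
) -> ValidationResult:
    """Classify a gene copy as functional or pseudogene with reasons.

    Pseudogene iff any of: exon-1 signal peptide absent; frameshift or
    internal stop in exon-2; terminal motif absent; or, for chimeric
    afgp/tlp genes, spacer motif absent or all tlp-derived exons deleted.
    Reasons enumerate every failed check.
    """
    checks = _checks(g, spacer_motif, terminal_motif)
    reasons = []
    if not checks["has_exon1_signal"]:
        reasons.append(REASON_NO_SIGNAL)
    if not checks["exon2_frame_intact"]:
        reasons.append(REASON_FRAME)
    if not checks["has_terminal_motif"]:
        reasons.append(REASON_NO_TERMINAL)
    if g.is_chimeric:
        if not checks["has_spacer_motif"]:
            reasons.append(REASON_NO_SPACER)
        if not checks["tlp_exons_present"]:
            reasons.append(REASON_NO_TLP)
    status = "pseudogene" if reasons else "functional"
    return ValidationResult(g.gene_id, status, tuple(reasons), checks)


# ---------------------------------------------------------------------------
# locus layout tokens


@dataclass(frozen=True)
class LocusToken:
    """One element of the locus token sequence: a gene or a repeat copy."""

    kind: str  # "gene" | "repeat"
    name: str  # gene id or repeat family
    strand: str | None = None
    interval: GenomicInterval | None = None
    gene_type: str | None = None  # for gene tokens

    def signature(self) -> tuple:
        """Identity used for motif detection: repeats collapse to family,
        gene tokens carry type and strand (not copy identity)."""
        if self.kind == "gene":
            return ("gene", self.gene_type or "gene", self.strand)
        return ("repeat", self.name)


@dataclass(frozen=True)
class LocusLayout:
    """Ordered, non-overlapping token sequence over an afgp locus."""

    tokens: tuple[LocusToken, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "tokens",
            tuple(
                sorted(
                    self.tokens,
                    key=lambda t: (t.interval.start if t.interval else 0),
                )
            ),
        )

    @property
    def gene_tokens(self) -> tuple[LocusToken, ...]:
        return tuple(t for t in self.tokens if t.kind == "gene")


# ---------------------------------------------------------------------------
# haplotype comparison


@dataclass(frozen=True)
class ExonLengthVariant:
    gene_hap1: str
    gene_hap2: str
    delta_bp: int  # len(exon2 hap1) - len(exon2 hap2)
    frame_preserving: bool


@dataclass(frozen=True)
class LocusComparison:
    matched: tuple[tuple[str, str], ...]
    unmatched_hap1: tuple[str, ...]
    unmatched_hap2: tuple[str, ...]
    variants: tuple[ExonLengthVariant, ...]


def _strand_runs(genes: Sequence[AfgpGeneModel]) -> list[list[AfgpGeneModel]]:
    runs: list[list[AfgpGeneModel]] = []
    for g in genes:
        if runs and runs[-1][-1].strand != g.strand:
            runs.append([g])
        elif not runs:
            runs.append([g])
        else:
            runs[-1].append(g)
    return runs


def compare_haplotype_loci(
    genes_hap1: Sequence[AfgpGeneModel],
    genes_hap2: Sequence[AfgpGeneModel],
    match_by: str = "order",
) -> LocusComparison:
    """Match gene copies across haplotypes and report length variants.

    Genes must be supplied in locus order (between the flanking anchor
    genes, identically oriented).  Default matching is positional within
    runs of constant strand — the two haplotypes of a tandem locus are
    expected to be nearly identical in structure — with a fallback
    ``match_by='exon1'`` mode pairing genes by best exon-1 sequence
    similarity when the order is perturbed.  Each matched pair reports the
    exon-2 length difference Δ and whether it preserves the reading frame
    (|Δ| mod 3 == 0); unmatched genes are presence/absence candidates.
    """
    if match_by not in ("order", "exon1"):
        raise ValueError(f"unknown match mode {match_by!r}")
    pairs: list[tuple[AfgpGeneModel, AfgpGeneModel]] = []
    un1: list[str] = []
    un2: list[str] = []
    if match_by == "order":
        runs1 = _strand_runs(genes_hap1)
        runs2 = _strand_runs(genes_hap2)
        for i in range(max(len(runs1), len(runs2))):
            r1 = runs1[i] if i < len(runs1) else []
            r2 = runs2[i] if i < len(runs2) else []
            n = min(len(r1), len(r2))
            pairs.extend(zip(r1[:n], r2[:n]))
            un1.extend(g.gene_id for g in r1[n:])
            un2.extend(g.gene_id for g in r2[n:])
    else:
        remaining = list(genes_hap2)
        scored = []
        for g1 in genes_hap1:
            for g2 in genes_hap2:
                s1, s2 = g1.exon1_seq or "", g2.exon1_seq or ""
                sim = difflib.SequenceMatcher(None, s1, s2).ratio() if s1 and s2 else 0.0
                scored.append((-sim, g1.gene_id, g2.gene_id, g1, g2))
        scored.sort(key=lambda t: (t[0], t[1], t[2]))
        used1: set[str] = set()
        used2: set[str] = set()
        for negsim, id1, id2, g1, g2 in scored:
            if -negsim <= 0 or id1 in used1 or id2 in used2:
                continue
            pairs.append((g1, g2))
            used1.add(id1)
            used2.add(id2)
        un1 = [g.gene_id for g in genes_hap1 if g.gene_id not in used1]
        un2 = [g.gene_id for g in genes_hap2 if g.gene_id not in used2]
    variants = []
    for g1, g2 in pairs:
        l1 = len(g1.exon2_seq or "")
        l2 = len(g2.exon2_seq or "")
        delta = l1 - l2
        if delta != 0:
            variants.append(
                ExonLengthVariant(
                    gene_hap1=g1.gene_id,
                    gene_hap2=g2.gene_id,
                    delta_bp=delta,
                    frame_preserving=(abs(delta) % 3 == 0),
                )
            )
    return LocusComparison(
        matched=tuple((g1.gene_id, g2.gene_id) for g1, g2 in pairs),
        unmatched_hap1=tuple(un1),
        unmatched_hap2=tuple(un2),
        variants=tuple(variants),
    )


# ---------------------------------------------------------------------------
# array and duplication-motif detection


@dataclass(frozen=True)
class AlternatingRun:
    """A maximal run of >= 4 genes with strictly alternating orientation."""

    gene_ids: tuple[str, ...]
    strands: str
    start_index: int  # index into the layout's gene-token order

    @property
    def length(self) -> int:
        return len(self.gene_ids)

    @property
    def pairs_of_pairs(self) -> int:
        return self.length // 4


def detect_alternating_arrays(
    layout: LocusLayout, min_run: int = 4
) -> list[AlternatingRun]:
    """Maximal runs of genes with strictly alternating strand.

    Runs are computed over the ordered gene tokens (interleaved repeat
    tokens do not break a run, matching the gene+TE architecture of the
    locus) and reported when at least ``min_run`` genes long.
    """
    genes = layout.gene_tokens
    runs: list[AlternatingRun] = []
    i = 0
    while i < len(genes):
        j = i + 1
        while j < len(genes) and genes[j].strand != genes[j - 1].strand:
            j += 1
        if j - i >= min_run:
            runs.append(
                AlternatingRun(
                    gene_ids=tuple(g.name for g in genes[i:j]),
                    strands="".join(g.strand or "?" for g in genes[i:j]),
                    start_index=i,
                )
            )
        i = j
    return runs


@dataclass(frozen=True)
class DuplicationMotif:
    """The best tandem-repeated token unit of the locus."""

    unit: tuple[tuple, ...]  # token signatures
    copies: int
    start_index: int
    score: int  # copies * unit length
    span: GenomicInterval | None


def detect_duplication_motif(
    layout: LocusLayout,
    min_unit: int = 2,
    min_gene_tokens: int = 2,
) -> DuplicationMotif | None:
    """Find the highest-scoring tandem exact-token repeat U^k (k >= 2).

    The unit must span at least ``min_unit`` tokens and contain at least
    ``min_gene_tokens`` gene tokens; the score maximized is
    copies x unit-length, with ties broken by more copies, then earlier
    start.  Returns ``None`` when nothing repeats.
    """
    sigs = [t.signature() for t in layout.tokens]
    n = len(sigs)
    best: tuple[int, int, int, int] | None = None  # (-score, -k, start, L)
    for L in range(min_unit, n // 2 + 1):
        for start in range(0, n - 2 * L + 1):
            unit = sigs[start : start + L]
            if sum(1 for s in unit if s[0] == "gene") < min_gene_tokens:
                continue
            k = 1
            while start + (k + 1) * L <= n and sigs[start + k * L : start + (k + 1) * L] == unit:
                k += 1
            if k >= 2:
                score = k * L
                cand = (-score, -k, start, L)
                if best is None or cand < best:
                    best = cand
    if best is None:
        return None
    _, negk, start, L = best
    k = -negk
    toks = layout.tokens[start : start + k * L]
    span = None
    if toks[0].interval is not None and toks[-1].interval is not None:
        span = GenomicInterval(
            toks[0].interval.chrom, toks[0].interval.start, toks[-1].interval.end
        )
    return DuplicationMotif(
        unit=tuple(sigs[start : start + L]),
        copies=k,
        start_index=start,
        score=k * L,
        span=span,
    )
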