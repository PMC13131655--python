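"""Readers and writers for the formats the pipeline touches.

Every other module consumes only the domain types produced here: BED and
GFF3 interval annotations, RepeatMasker-style repeat tables with per-copy
divergence, Syri-style structural-variant tables, dated newick trees,
HAL-style branch-mutation tables, and bedGraph-like per-species alignment
depth tracks.

Table dialects are fixed, header-first TSVs documented per reader; the
upstream tools emit heterogeneous formats, so the package pins one dialect
per table type.  Parsers reject malformed input with the offending line
number — they never silently repair.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import dendropy

from .intervals import CoverageIndex, GenomicInterval, IntervalError

__all__ = [
    "FormatError",
    "RepeatHit",
    "SVRecord",
    "GeneModel",
    "DatedTree",
    "BranchMutation",
    "DepthTrack",
    "REPEAT_CLASSES",
    "SV_TYPES",
    "read_bed",
    "write_bed",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_features",
    "read_repeat_table",
    "write_repeat_table",
    "read_sv_table",
    "write_sv_table",
    "read_dated_tree",
    "write_dated_tree",
    "read_branch_mutations",
    "write_branch_mutations",
    "read_depth_track",
    "read_depth_tracks",
    "write_depth_track",
]

REPEAT_CLASSES = frozenset({"DNA", "LINE", "LTR", "SINE", "tandem", "simple", "other"})
SV_TYPES = frozenset({"INS", "DEL", "INV", "DUP", "TRA"})
GENOTYPES = frozenset({"het", "hom_alt", "unknown"})
SOURCES = frozenset({"assembly", "reads"})


class FormatError(ValueError):
    """Malformed input file; message carries the file and line number."""


@dataclass(frozen=True)
class RepeatHit:
    """One repeat copy: interval, family, class, divergence and score.

    ``divergence_pct`` is the CpG-corrected Kimura distance (%) of the copy
    from its family consensus, supplied by the upstream annotation and used
    as a proxy for insertion age.
    """

    interval: GenomicInterval
    family: str
    class_label: str
    divergence_pct: float
    score: float

    def __post_init__(self) -> None:
        if self.class_label not in REPEAT_CLASSES:
            raise FormatError(
                f"unknown repeat class {self.class_label!r} (expected one of {sorted(REPEAT_CLASSES)})"
            )
        if self.divergence_pct < 0:
            raise FormatError(f"negative divergence {self.divergence_pct}")


@dataclass(frozen=True)
class SVRecord:
    """A structural variant relative to the reference haplotype.

    Deletions/inversions/duplications carry reference coordinates; an
    insertion carries a 1-bp anchor on the reference plus the inserted
    length.  For insertions, :meth:`span` projects the inserted sequence as
    ``[anchor_start, anchor_start + length_bp)`` — the carrier-haplotype
    coordinate convention used when intersecting with the carrier's repeat
    annotation.
    """

    sv_type: str
    ref_interval: GenomicInterval
    length_bp: int
    genotype: str = "unknown"
    source: str = "assembly"

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise FormatError(f"unknown SV type {self.sv_type!r}")
        if self.length_bp <= 0:
            raise FormatError(f"SV length must be positive, got {self.length_bp}")
        if self.genotype not in GENOTYPES:
            raise FormatError(f"unknown genotype {self.genotype!r}")
        if self.source not in SOURCES:
            raise FormatError(f"unknown source {self.source!r}")

    def span(self) -> GenomicInterval:
        """Full-length footprint of the variant (anchor-projected for INS)."""
        if self.sv_type == "INS":
            s = self.ref_interval.start
            return GenomicInterval(self.ref_interval.chrom, s, s + self.length_bp)
        return self.ref_interval


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: stranded span plus its exon intervals."""

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(sorted(self.exons, key=lambda e: e.start)))
        for e in self.exons:
            if e.chrom != self.interval.chrom:
                raise FormatError(f"exon of {self.gene_id} on wrong chromosome")

    @property
    def strand(self) -> str | None:
        return self.interval.strand

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.interval.chrom, a.end, b.start))
        return tuple(out)

    @property
    def tss(self) -> int:
        """Transcription start position (strand-aware)."""
        return self.interval.start if self.strand != "-" else self.interval.end - 1

    @property
    def tts(self) -> int:
        """Transcription termination position (strand-aware)."""
        return self.interval.end - 1 if self.strand != "-" else self.interval.start


@dataclass(frozen=True)
class BranchMutation:
    """An insertion or deletion assigned to one branch of the species tree."""

    branch_id: str
    kind: str
    bp: int
    lifted_interval: GenomicInterval | None = None
    event_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise FormatError(f"mutation kind must be insertion/deletion, got {self.kind!r}")
        if self.bp <= 0:
            raise FormatError(f"mutation extent must be positive, got {self.bp}")


class DatedTree:
    """A rooted species tree with node ages (MYA) and branch durations (MY).

    Leaves are anchored at age 0; the age of an internal node is the maximum
    over children of (child age + child branch length), so ultrametry is not
    required.  Branches are identified by the sorted, ``+``-joined leaf names
    of the subtending clade (a leaf branch is just the leaf name).
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.ages: dict[str, float] = {}
        self.durations: dict[str, float] = {}
        self.parent: dict[str, str | None] = {}
        self._leafsets: dict[str, frozenset[str]] = {}
        for node in tree.postorder_node_iter():
            if node.parent_node is not None:
                if node.edge.length is None or node.edge.length <= 0:
                    raise FormatError(
                        f"branch above {self.branch_id(node)} has non-positive length"
                    )
        for node in tree.postorder_node_iter():
            bid = self.branch_id(node)
            if node.is_leaf():
                self.ages[bid] = 0.0
            else:
                self.ages[bid] = max(
                    self.ages[self.branch_id(c)] + c.edge.length
                    for c in node.child_nodes()
                )
        for node in tree.postorder_node_iter():
            bid = self.branch_id(node)
            if node.parent_node is not None:
                self.durations[bid] = float(node.edge.length)
                self.parent[bid] = self.branch_id(node.parent_node)
            else:
                self.parent[bid] = None
        self.root_id = self.branch_id(tree.seed_node)

    def branch_id(self, node: dendropy.Node) -> str:
        key = id(node)
        if node.is_leaf():
            return node.taxon.label
        cached = getattr(node, "_notokit_bid", None)
        if cached is None:
            cached = "+".join(sorted(lf.taxon.label for lf in node.leaf_iter()))
            node._notokit_bid = cached
        return cached

    @property
    def leaves(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def branch_ids(self) -> list[str]:
        return list(self.durations)

    def parent_age(self, branch_id: str) -> float:
        return self.ages[branch_id] + self.durations[branch_id]

    def path_to_leaf(self, leaf: str) -> list[str]:
        """Branch ids from the root-adjacent branch down to ``leaf``."""
        if leaf not in set(self.leaves):
            raise KeyError(f"leaf {leaf!r} not in tree")
        path = []
        cur: str | None = leaf
        while cur is not None and cur != self.root_id:
            path.append(cur)
            cur = self.parent[cur]
        return list(reversed(path))


@dataclass(frozen=True)
class DepthTrack:
    """Presence/absence of alignment per base for one species.

    Built from bedGraph-like intervals; a base is covered when its depth
    value is positive.
    """

    species: str
    intervals: tuple[GenomicInterval, ...]
    _index: CoverageIndex = field(init=False, repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(self.intervals))
        object.__setattr__(self, "_index", CoverageIndex(self.intervals))

    def covered_fraction(self, interval: GenomicInterval) -> float:
        return float(self._index.covered_bp(interval.chrom, interval.start, interval.end)) / interval.length


# ---------------------------------------------------------------------------
# line-oriented TSV helpers


def _rows(path: str | Path, expected_header: Sequence[str]):
    """Yield (path, lineno, fields) for data rows of a header-first TSV."""
    path = Path(path)
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if fields != list(expected_header):
                    raise FormatError(
                        f"{path}:{lineno}: expected header {list(expected_header)}, got {fields}"
                    )
                header_seen = True
                continue
            yield path, lineno, fields


def _int(path, lineno, value, what) -> int:
    try:
        return int(value)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: {what} is not an integer: {value!r}") from None


def _float(path, lineno, value, what) -> float:
    try:
        return float(value)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: {what} is not a number: {value!r}") from None


def _interval(path, lineno, chrom, start, end, strand=None) -> GenomicInterval:
    try:
        return GenomicInterval(chrom, start, end, strand)
    except IntervalError as exc:
        raise FormatError(f"{path}:{lineno}: {exc}") from None


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED (0-based half-open); columns 1-3 required, 4-6 honored."""
    out = []
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            strand = f[5] if len(f) >= 6 and f[5] in ("+", "-") else None
            out.append(
                _interval(
                    path, lineno, f[0],
                    _int(path, lineno, f[1], "start"),
                    _int(path, lineno, f[2], "end"),
                    strand,
                )
            )
    return out


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval], names: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand or '.'}\n")


# ---------------------------------------------------------------------------
# GFF3 gene models


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Parse GFF3 gene/mRNA/exon rows into gene models.

    1-based inclusive GFF3 coordinates are converted to the internal 0-based
    half-open convention.  Exons may point at an mRNA (whose ``Parent`` is a
    gene) or directly at a gene.
    """
    path = Path(path)
    genes: dict[str, dict] = {}
    feature_gene: dict[str, str] = {}  # feature ID -> owning gene ID
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise FormatError(f"{path}:{lineno}: GFF3 needs 9 columns, got {len(f)}")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = f
            start = _int(path, lineno, start, "start")
            end = _int(path, lineno, end, "end")
            if start < 1 or end < start:
                raise FormatError(f"{path}:{lineno}: bad GFF3 coordinates {start}..{end}")
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
            )
            strand = strand if strand in ("+", "-") else None
            if ftype == "gene":
                gid = attr.get("ID")
                if gid is None:
                    raise FormatError(f"{path}:{lineno}: gene without ID")
                genes[gid] = {
                    "interval": _interval(path, lineno, chrom, start - 1, end, strand),
                    "exons": [],
                }
                feature_gene[gid] = gid
                order.append(gid)
            elif ftype in ("mRNA", "transcript"):
                fid, parent = attr.get("ID"), attr.get("Parent")
                if parent not in feature_gene:
                    raise FormatError(f"{path}:{lineno}: {ftype} with unknown Parent {parent!r}")
                if fid:
                    feature_gene[fid] = feature_gene[parent]
            elif ftype in ("exon", "CDS"):
                parent = attr.get("Parent")
                if parent not in feature_gene:
                    raise FormatError(f"{path}:{lineno}: {ftype} with unknown Parent {parent!r}")
                if ftype == "exon":
                    gid = feature_gene[parent]
                    genes[gid]["exons"].append(
                        _interval(path, lineno, chrom, start - 1, end, strand)
                    )
            # other feature types are ignored
    return [
        GeneModel(gene_id=gid, interval=genes[gid]["interval"], exons=tuple(genes[gid]["exons"]))
        for gid in order
    ]


def write_gff3_genes(path: str | Path, genes: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            strand = iv.strand or "."
            fh.write(
                f"{iv.chrom}\tnotokit\tgene\t{iv.start + 1}\t{iv.end}\t.\t{strand}\t.\tID={g.gene_id}\n"
            )
            mid = f"{g.gene_id}.t1"
            fh.write(
                f"{iv.chrom}\tnotokit\tmRNA\t{iv.start + 1}\t{iv.end}\t.\t{strand}\t.\tID={mid};Parent={g.gene_id}\n"
            )
            for k, e in enumerate(g.exons, start=1):
                fh.write(
                    f"{iv.chrom}\tnotokit\texon\t{e.start + 1}\t{e.end}\t.\t{strand}\t.\t"
                    f"ID={mid}.exon{k};Parent={mid}\n"
                )


def read_features(path: str | Path, format: str):
    """Dispatch to the reader for a declared annotation format.

    ``BED`` -> intervals, ``GFF3`` -> gene models, ``repeat_table`` ->
    RepeatHit records.
    """
    readers = {"BED": read_bed, "GFF3": read_gff3_genes, "repeat_table": read_repeat_table}
    if format not in readers:
        raise ValueError(f"unknown format {format!r} (expected one of {sorted(readers)})")
    return readers[format](path)


# ---------------------------------------------------------------------------
# repeat table

_REPEAT_HEADER = ["chrom", "start", "end", "strand", "family", "class_label", "divergence_pct", "score"]


def read_repeat_table(path: str | Path) -> list[RepeatHit]:
    """TSV dialect: chrom, start, end, strand, family, class_label, divergence_pct, score."""
    out = []
    for p, ln, f in _rows(path, _REPEAT_HEADER):
        if len(f) != 8:
            raise FormatError(f"{p}:{ln}: expected 8 columns, got {len(f)}")
        strand = f[3] if f[3] in ("+", "-") else None
        try:
            out.append(
                RepeatHit(
                    interval=_interval(p, ln, f[0], _int(p, ln, f[1], "start"), _int(p, ln, f[2], "end"), strand),
                    family=f[4],
                    class_label=f[5],
                    divergence_pct=_float(p, ln, f[6], "divergence_pct"),
                    score=_float(p, ln, f[7], "score"),
                )
            )
        except FormatError as exc:
            raise FormatError(f"{p}:{ln}: {exc}") from None
    return out


def write_repeat_table(path: str | Path, hits: Iterable[RepeatHit]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_REPEAT_HEADER) + "\n")
        for h in hits:
            iv = h.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand or '.'}\t{h.family}\t"
                f"{h.class_label}\t{h.divergence_pct:g}\t{h.score:g}\n"
            )


# ---------------------------------------------------------------------------
# SV table

_SV_HEADER = ["chrom", "start", "end", "sv_type", "length", "genotype", "source"]


def read_sv_table(path: str | Path) -> list[SVRecord]:
    """Syri-style TSV dialect: chrom, start, end, sv_type, length, genotype, source."""
    out = []
    for p, ln, f in _rows(path, _SV_HEADER):
        if len(f) != 7:
            raise FormatError(f"{p}:{ln}: expected 7 columns, got {len(f)}")
        try:
            out.append(
                SVRecord(
                    sv_type=f[3],
                    ref_interval=_interval(p, ln, f[0], _int(p, ln, f[1], "start"), _int(p, ln, f[2], "end")),
                    length_bp=_int(p, ln, f[4], "length"),
                    genotype=f[5],
                    source=f[6],
                )
            )
        except FormatError as exc:
            raise FormatError(f"{p}:{ln}: {exc}") from None
    return out


def write_sv_table(path: str | Path, svs: Iterable[SVRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_SV_HEADER) + "\n")
        for sv in svs:
            iv = sv.ref_interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{sv.sv_type}\t{sv.length_bp}\t{sv.genotype}\t{sv.source}\n"
            )


# ---------------------------------------------------------------------------
# dated tree


def read_dated_tree(source: str | Path) -> DatedTree:
    """Read a rooted newick tree with branch lengths in MY.

    ``source`` may be a path or a newick string.
    """
    text = None
    if isinstance(source, Path) or (isinstance(source, str) and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    tree = dendropy.Tree.get(data=text, schema="newick", rooting="force-rooted")
    return DatedTree(tree)


def write_dated_tree(path: str | Path, dated: DatedTree) -> None:
    Path(path).write_text(dated.tree.as_string(schema="newick", suppress_rooting=True))


# ---------------------------------------------------------------------------
# branch mutations

_BM_HEADER = ["branch_id", "kind", "bp", "chrom", "start", "end", "event_id"]


def read_branch_mutations(path: str | Path) -> list[BranchMutation]:
    """TSV dialect: branch_id, kind, bp, chrom, start, end, event_id.

    Deletions (not lifted) use ``.`` in the coordinate and event columns.
    """
    out = []
    for p, ln, f in _rows(path, _BM_HEADER):
        if len(f) != 7:
            raise FormatError(f"{p}:{ln}: expected 7 columns, got {len(f)}")
        lifted = None
        if f[3] != ".":
            lifted = _interval(p, ln, f[3], _int(p, ln, f[4], "start"), _int(p, ln, f[5], "end"))
        try:
            out.append(
                BranchMutation(
                    branch_id=f[0],
                    kind=f[1],
                    bp=_int(p, ln, f[2], "bp"),
                    lifted_interval=lifted,
                    event_id=None if f[6] == "." else f[6],
                )
            )
        except FormatError as exc:
            raise FormatError(f"{p}:{ln}: {exc}") from None
    return out


def write_branch_mutations(path: str | Path, muts: Iterable[BranchMutation]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_BM_HEADER) + "\n")
        for m in muts:
            if m.lifted_interval is not None:
                iv = m.lifted_interval
                coords = f"{iv.chrom}\t{iv.start}\t{iv.end}"
            else:
                coords = ".\t0\t0"
            fh.write(f"{m.branch_id}\t{m.kind}\t{m.bp}\t{coords}\t{m.event_id or '.'}\n")


# ---------------------------------------------------------------------------
# depth tracks


def read_depth_track(path: str | Path, species: str) -> DepthTrack:
    """bedGraph-like TSV: chrom, start, end, depth; covered where depth > 0."""
    covered = []
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) != 4:
                raise FormatError(f"{path}:{lineno}: bedGraph needs 4 columns")
            depth = _float(path, lineno, f[3], "depth")
            if depth > 0:
                covered.append(
                    _interval(path, lineno, f[0], _int(path, lineno, f[1], "start"), _int(path, lineno, f[2], "end"))
                )
    return DepthTrack(species=species, intervals=tuple(covered))


def read_depth_tracks(paths: Mapping[str, str | Path]) -> dict[str, DepthTrack]:
    return {sp: read_depth_track(p, sp) for sp, p in paths.items()}


def write_depth_track(path: str | Path, track: DepthTrack) -> None:
    with open(path, "w") as fh:
        for iv in sorted(track.intervals, key=lambda i: (i.chrom, i.start)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t1\n")
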