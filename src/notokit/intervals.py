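"""Coordinate arithmetic on genomic intervals.

Every module in the package funnels its positional logic through this one:
reciprocal overlaps, gap-bounded merging, score-based overlap resolution,
windowed coverage fractions, nearest-feature distances, and seeded interval
randomization for shuffled controls.

Conventions
-----------
* All coordinates are 0-based, half-open ``[start, end)``; GFF3 input
  (1-based, inclusive) is converted at I/O time, never here.
* "closer than N bp" merges on a *strict* gap inequality (``gap < N``).
* "at least 75%" style thresholds are inclusive (``>= threshold``).
"""

from __future__ import annotations

import heapq
from collections.abc import Callable, Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

__all__ = [
    "GenomicInterval",
    "GenomeLayout",
    "IntervalError",
    "PlacementError",
    "MergedInterval",
    "CoverageIndex",
    "reciprocal_overlap",
    "passes_reciprocal",
    "merge_within",
    "resolve_overlaps_by_score",
    "feature_fraction",
    "distance_to_nearest",
    "distance_to_chrom_end",
    "shuffle_intervals",
]


class IntervalError(ValueError):
    """Raised for malformed intervals or layouts."""


class PlacementError(RuntimeError):
    """Raised when a randomized interval cannot be placed anywhere."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based, half-open interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise IntervalError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise IntervalError(
                f"degenerate interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in (None, "+", "-"):
            raise IntervalError(f"strand must be '+', '-' or None, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 on different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:  # pragma: no cover - convenience alias
        return self.length


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome sizes plus optional assembly-gap intervals.

    The layout supplies the denominators for chromosome-end distances and the
    permitted placement space for shuffled control intervals.
    """

    chrom_lengths: Mapping[str, int]
    gaps: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise IntervalError("layout needs at least one chromosome")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise IntervalError(f"chromosome {chrom} has non-positive length {length}")
        object.__setattr__(self, "gaps", tuple(self.gaps))
        for gap in self.gaps:
            if gap.chrom not in self.chrom_lengths:
                raise IntervalError(f"gap on unknown chromosome {gap.chrom}")
            if gap.end > self.chrom_lengths[gap.chrom]:
                raise IntervalError(f"gap {gap} extends past chromosome end")

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_lengths.values())

    def allowed_segments(self, chrom: str, exclude_gaps: bool = True) -> list[tuple[int, int]]:
        """Half-open segments of ``chrom`` outside any assembly gap."""
        length = self.chrom_lengths[chrom]
        if not exclude_gaps:
            return [(0, length)]
        gaps = sorted(
            (g.start, g.end) for g in self.gaps if g.chrom == chrom
        )
        segments: list[tuple[int, int]] = []
        cursor = 0
        for gs, ge in gaps:
            if gs > cursor:
                segments.append((cursor, gs))
            cursor = max(cursor, ge)
        if cursor < length:
            segments.append((cursor, length))
        return segments


@dataclass(frozen=True)
class MergedInterval:
    """A merged interval plus the group key and input indices it absorbed."""

    interval: GenomicInterval
    key: Any = None
    members: tuple[int, ...] = ()


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> tuple[float, float]:
    """Overlap of ``a`` and ``b`` as fractions of each interval's own length.

    Returns ``(overlap/len(a), overlap/len(b))``; ``(0.0, 0.0)`` when the
    intervals sit on different chromosomes.
    """
    ov = a.overlap_bp(b)
    return ov / a.length, ov / b.length


def passes_reciprocal(
    a: GenomicInterval, b: GenomicInterval, threshold: float = 0.75
) -> bool:
    """True iff both reciprocal fractions reach ``threshold`` (inclusive)."""
    fa, fb = reciprocal_overlap(a, b)
    return fa >= threshold and fb >= threshold


def merge_within(
    intervals: Sequence[GenomicInterval],
    max_gap: int,
    keys: Sequence[Any] | None = None,
) -> list[MergedInterval]:
    """Merge intervals whose gap is strictly below ``max_gap``.

    Two intervals merge iff they share a chromosome, the same group key (when
    ``keys`` is given), and the gap between them is ``< max_gap``; overlapping
    or touching intervals always merge when ``max_gap > 0`` and merge on
    overlap alone when ``max_gap == 0``.  Output is disjoint per group and
    sorted by position.
    """
    if max_gap < 0:
        raise IntervalError("max_gap must be >= 0")
    if keys is not None and len(keys) != len(intervals):
        raise IntervalError("keys must parallel intervals")
    decorated = [
        (iv.chrom, iv.start, iv.end, i, None if keys is None else keys[i])
        for i, iv in enumerate(intervals)
    ]
    groups: dict[Any, list[tuple[str, int, int, int]]] = {}
    for chrom, start, end, idx, key in decorated:
        groups.setdefault((key, chrom), []).append((chrom, start, end, idx))
    out: list[MergedInterval] = []
    for (key, _chrom), items in groups.items():
        items.sort(key=lambda t: (t[1], t[2]))
        cur_chrom, cur_start, cur_end, idx0 = items[0]
        members = [idx0]
        for chrom, start, end, idx in items[1:]:
            gap = start - cur_end
            if gap < max_gap or gap < 0 or (max_gap == 0 and gap < 0):
                cur_end = max(cur_end, end)
                members.append(idx)
            else:
                out.append(
                    MergedInterval(
                        GenomicInterval(cur_chrom, cur_start, cur_end),
                        key=key,
                        members=tuple(members),
                    )
                )
                cur_start, cur_end, members = start, end, [idx]
        out.append(
            MergedInterval(
                GenomicInterval(cur_chrom, cur_start, cur_end),
                key=key,
                members=tuple(members),
            )
        )
    out.sort(key=lambda m: (m.interval.chrom, m.interval.start, m.interval.end))
    return out


def resolve_overlaps_by_score(hits: Sequence[Any]) -> list[Any]:
    """Reduce overlapping scored hits to a disjoint annotation.

    At every base the retained hit is the one with the highest ``score``;
    ties break by earlier start, then input order.  Losing hits are truncated
    to their uncovered pieces or dropped entirely.  ``hits`` may be any
    dataclass instances exposing ``interval`` and ``score`` attributes; output
    items are copies with (possibly) truncated intervals.
    """
    by_chrom: dict[str, list[int]] = {}
    for i, h in enumerate(hits):
        by_chrom.setdefault(h.interval.chrom, []).append(i)
    out: list[Any] = []
    for chrom in sorted(by_chrom):
        idxs = by_chrom[chrom]
        bounds = sorted({b for i in idxs for b in (hits[i].interval.start, hits[i].interval.end)})
        starts = sorted(idxs, key=lambda i: hits[i].interval.start)
        heap: list[tuple[tuple[float, int, int], int, int]] = []  # (prio, end, idx)
        si = 0
        pieces: list[tuple[int, int, int]] = []  # (start, end, winner idx)
        for seg_start, seg_end in zip(bounds, bounds[1:]):
            while si < len(starts) and hits[starts[si]].interval.start <= seg_start:
                i = starts[si]
                prio = (-hits[i].score, hits[i].interval.start, i)
                heapq.heappush(heap, (prio, hits[i].interval.end, i))
                si += 1
            while heap and heap[0][1] <= seg_start:
                heapq.heappop(heap)
            if heap:
                winner = heap[0][2]
                if pieces and pieces[-1][1] == seg_start and pieces[-1][2] == winner:
                    pieces[-1] = (pieces[-1][0], seg_end, winner)
                else:
                    pieces.append((seg_start, seg_end, winner))
        for start, end, i in pieces:
            iv = hits[i].interval
            out.append(replace(hits[i], interval=replace(iv, start=start, end=end)))
    return out


class CoverageIndex:
    """Union coverage of an interval set, queryable in O(log n) per window.

    Built once from a (possibly self-overlapping) annotation; answers
    "how many bases of ``[start, end)`` are covered" via prefix sums over the
    merged intervals.  Used for 50-kb flank feature densities and per-species
    alignment-depth fractions, where per-query scans would be too slow.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._cum: dict[str, np.ndarray] = {}
        for chrom, items in per_chrom.items():
            items.sort()
            merged: list[tuple[int, int]] = []
            for s, e in items:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            starts = np.array([s for s, _ in merged], dtype=np.int64)
            ends = np.array([e for _, e in merged], dtype=np.int64)
            cum = np.concatenate([[0], np.cumsum(ends - starts)])
            self._starts[chrom], self._ends[chrom], self._cum[chrom] = starts, ends, cum

    def covered_bp(self, chrom: str, start, end):
        """Covered bases of ``[start, end)``; accepts scalars or arrays."""
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        if chrom not in self._starts:
            return np.zeros_like(start) if start.ndim else 0
        s, e, cum = self._starts[chrom], self._ends[chrom], self._cum[chrom]
        # prefix coverage up to position x
        def prefix(x):
            i = np.searchsorted(e, x, side="left")  # intervals fully before x
            base = cum[i]
            # partial interval containing x
            j = np.searchsorted(s, x, side="right") - 1
            partial = np.where(
                (j >= 0) & (j >= i), np.maximum(0, x - s[np.maximum(j, 0)]), 0
            )
            return base + partial

        res = prefix(end) - prefix(start)
        return res if res.ndim else int(res)

    def fraction(self, chrom: str, start, end):
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        cov = self.covered_bp(chrom, start, end)
        frac = cov / np.maximum(1, end - start)
        return frac if np.ndim(frac) else float(frac)


def feature_fraction(
    window: GenomicInterval,
    annotation: Sequence[GenomicInterval] | CoverageIndex,
    layout: GenomeLayout | None = None,
) -> float:
    """Fraction of ``window`` bases covered by the union of ``annotation``.

    With a ``layout``, the window is clipped at the chromosome boundary and
    the clipped length becomes the denominator; a window lying entirely
    outside its chromosome is an input error.
    """
    start, end = window.start, window.end
    if layout is not None:
        if window.chrom not in layout.chrom_lengths:
            raise IntervalError(f"window on unknown chromosome {window.chrom}")
        clen = layout.chrom_lengths[window.chrom]
        if start >= clen:
            raise IntervalError(f"window {window} lies outside its chromosome")
        end = min(end, clen)
    index = annotation if isinstance(annotation, CoverageIndex) else CoverageIndex(annotation)
    return float(index.covered_bp(window.chrom, start, end)) / (end - start)


def distance_to_nearest(
    x: GenomicInterval, targets: Sequence[GenomicInterval]
) -> int | None:
    """Minimum gap in bp from ``x`` to any same-chromosome target.

    0 when overlapping or touching a target; ``None`` (never an exception)
    when the chromosome carries no target at all.
    """
    best: int | None = None
    for t in targets:
        if t.chrom != x.chrom:
            continue
        if x.overlap_bp(t) > 0:
            return 0
        gap = max(t.start - x.end, x.start - t.end, 0)
        if best is None or gap < best:
            best = gap
    return best


def distance_to_chrom_end(x: GenomicInterval, layout: GenomeLayout) -> int:
    """``min(start, chrom_len - end)`` — distance to the closer chromosome end."""
    if x.chrom not in layout.chrom_lengths:
        raise IntervalError(f"interval on unknown chromosome {x.chrom}")
    clen = layout.chrom_lengths[x.chrom]
    if x.end > clen:
        raise IntervalError(f"interval {x} extends past chromosome end {clen}")
    return min(x.start, clen - x.end)


def shuffle_intervals(
    intervals: Sequence[GenomicInterval],
    layout: GenomeLayout,
    seed: int | np.random.Generator,
    exclude_gaps: bool = True,
    preserve_chromosome: bool = False,
) -> list[GenomicInterval]:
    """Length-preserving uniform randomization of intervals over the layout.

    Each input interval is re-placed uniformly over every permitted start
    position in the genome (or on its own chromosome when
    ``preserve_chromosome``), never intersecting an assembly gap when
    ``exclude_gaps``.  Deterministic for a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    segments_by_chrom = {
        c: layout.allowed_segments(c, exclude_gaps=exclude_gaps) for c in layout.chroms
    }
    out: list[GenomicInterval] = []
    for iv in intervals:
        chroms = [iv.chrom] if preserve_chromosome else layout.chroms
        slots: list[tuple[str, int, int]] = []  # (chrom, seg_start, n_starts)
        total = 0
        for c in chroms:
            for seg_start, seg_end in segments_by_chrom[c]:
                n = seg_end - seg_start - iv.length + 1
                if n > 0:
                    slots.append((c, seg_start, n))
                    total += n
        if total == 0:
            raise PlacementError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} (len {iv.length}) "
                "fits in no permitted span"
            )
        pick = int(rng.integers(total))
        for c, seg_start, n in slots:
            if pick < n:
                out.append(GenomicInterval(c, seg_start + pick, seg_start + pick + iv.length, iv.strand))
                break
            pick -= n
    return out
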