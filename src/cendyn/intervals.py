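"""Genomic coordinate types and interval-set algebra.

All coordinates are 0-based, half-open ``[start, end)`` — the BED convention.
Interval sets are plain lists of :class:`GenomicInterval`; every set-algebra
operation returns a sorted, disjoint list on the same convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

__all__ = [
    "GenomicInterval",
    "ChromSizes",
    "intersect",
    "subtract",
    "merge",
    "union",
    "interval_algebra",
    "annotate_overlaps",
    "total_length",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = field(default=None, compare=False)
    score: Optional[float] = field(default=None, compare=False)
    strand: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand is not None and self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of + - . , got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def expanded(self, flank: int, chrom_length: Optional[int] = None) -> "GenomicInterval":
        """Interval extended by ``flank`` bp on both sides, clipped to bounds."""
        if flank < 0:
            raise ValueError("flank must be >= 0")
        start = max(0, self.start - flank)
        end = self.end + flank
        if chrom_length is not None:
            end = min(end, chrom_length)
        return replace(self, start=start, end=end)


class ChromSizes(Dict[str, int]):
    """Mapping chromosome name -> length in bp."""

    def __init__(self, sizes: Mapping[str, int]):
        for chrom, length in sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length")
        super().__init__(sizes)

    def validate(self, interval: GenomicInterval) -> None:
        if interval.chrom not in self:
            raise KeyError(f"unknown chromosome {interval.chrom!r}")
        if interval.end > self[interval.chrom]:
            raise ValueError(
                f"interval {interval} extends past chromosome end "
                f"({self[interval.chrom]} bp)"
            )


def _by_chrom(ivs: Iterable[GenomicInterval]) -> Dict[str, List[GenomicInterval]]:
    out: Dict[str, List[GenomicInterval]] = {}
    for iv in ivs:
        out.setdefault(iv.chrom, []).append(iv)
    for lst in out.values():
        lst.sort(key=lambda iv: (iv.start, iv.end))
    return out


def merge(ivs: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    """Merge overlapping *or touching* intervals into a disjoint sorted set."""
    grouped = _by_chrom(ivs)
    out: List[GenomicInterval] = []
    for chrom in sorted(grouped):
        cur_s = cur_e = None
        for iv in grouped[chrom]:
            if cur_s is None:
                cur_s, cur_e = iv.start, iv.end
            elif iv.start <= cur_e:  # touching counts as mergeable
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        if cur_s is not None:
            out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def union(a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    return merge(list(a) + list(b))


def intersect(a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    """Intersection of two interval sets (half-open: touching != overlapping)."""
    am, bm = _by_chrom(merge(a)), _by_chrom(merge(b))
    out: List[GenomicInterval] = []
    for chrom in sorted(set(am) & set(bm)):
        xs, ys = am[chrom], bm[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            s = max(xs[i].start, ys[j].start)
            e = min(xs[i].end, ys[j].end)
            if s < e:
                out.append(GenomicInterval(chrom, s, e))
            if xs[i].end < ys[j].end:
                i += 1
            else:
                j += 1
    return out


def subtract(a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    """Parts of ``a`` not covered by ``b``."""
    am, bm = _by_chrom(merge(a)), _by_chrom(merge(b))
    out: List[GenomicInterval] = []
    for chrom in sorted(am):
        cuts = bm.get(chrom, [])
        for iv in am[chrom]:
            pos = iv.start
            for c in cuts:
                if c.end <= pos or c.start >= iv.end:
                    continue
                if c.start > pos:
                    out.append(GenomicInterval(chrom, pos, c.start))
                pos = max(pos, c.end)
            if pos < iv.end:
                out.append(GenomicInterval(chrom, pos, iv.end))
    return out


_OPS = {"intersect": intersect, "subtract": subtract, "union": union}


def interval_algebra(
    a: Iterable[GenomicInterval],
    b: Iterable[GenomicInterval],
    op: str,
) -> List[GenomicInterval]:
    """Dispatch ``intersect | subtract | merge | union`` by name.

    ``merge`` ignores ``b`` beyond pooling it with ``a``.
    """
    if op == "merge":
        return merge(list(a) + list(b))
    if op not in _OPS:
        raise ValueError(f"unknown op {op!r}; expected intersect/subtract/merge/union")
    return _OPS[op](a, b)


def total_length(ivs: Iterable[GenomicInterval]) -> int:
    """Total bp covered (intervals merged first so overlap is not double-counted)."""
    return sum(iv.width for iv in merge(ivs))


def annotate_overlaps(
    features: Sequence[GenomicInterval],
    hits: Sequence[GenomicInterval],
    flank: int = 0,
) -> List[Tuple[GenomicInterval, int, List[str]]]:
    """Count hits overlapping each feature extended by ``flank`` bp per side.

    Returns one row per feature: ``(feature, n_hits, hit_names)``.  Hit names
    fall back to ``chrom:start-end`` when the hit carries no label.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    hits_by_chrom = _by_chrom(hits)
    rows: List[Tuple[GenomicInterval, int, List[str]]] = []
    for feat in features:
        ext = feat.expanded(flank)
        ids = [
            h.name if h.name else f"{h.chrom}:{h.start}-{h.end}"
            for h in hits_by_chrom.get(feat.chrom, [])
            if h.start < ext.end and ext.start < h.end
        ]
        rows.append((feat, len(ids), ids))
    return rows
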