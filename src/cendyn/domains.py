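"""CENH3 enrichment-domain calling and centromere contraction analysis.

The functional centromere is taken as the chromosomal region whose binned
ChIP/Input fold change exceeds a threshold (default 4): maximal runs of
above-threshold bins are merged across small gaps and reported as
enrichment domains.  Parent and derived domains are compared by size and by
which arm side the lost sequence falls on, and the parental centromere is
partitioned into variable (R1, CENH3 binding lost in at least one derived
line) and stable (R2, binding retained in all lines) regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .intervals import GenomicInterval, intersect, merge, subtract, total_length
from .windows import CoverageTrack

__all__ = [
    "EnrichmentDomain",
    "DomainComparison",
    "CentromerePartition",
    "compute_bin_enrichment",
    "call_enrichment_domains",
    "compare_domains",
    "partition_variable_stable",
]


@dataclass(frozen=True)
class EnrichmentDomain:
    """A called CENH3-binding domain."""

    interval: GenomicInterval
    mean_fc: float
    peak_fc: float
    n_bins: int
    sample: str = ""

    @property
    def width(self) -> int:
        return self.interval.width


@dataclass
class DomainComparison:
    """Size and directionality comparison of a parent vs derived domain."""

    parent: EnrichmentDomain
    derived: EnrichmentDomain
    size_delta: int  # parent width - derived width
    retained_bp: int
    retained_fraction: float
    lost_short_arm_bp: int
    lost_long_arm_bp: int
    direction: str  # long-arm | short-arm | both | none


@dataclass
class CentromerePartition:
    """Variable (R1) vs stable (R2) partition of a parental centromere."""

    r1: List[GenomicInterval]
    r2: List[GenomicInterval]

    @property
    def r1_bp(self) -> int:
        return total_length(self.r1)

    @property
    def r2_bp(self) -> int:
        return total_length(self.r2)


def compute_bin_enrichment(
    chip: CoverageTrack, input_track: CoverageTrack, pseudocount: float = 1.0
) -> np.ndarray:
    """Per-window ChIP/Input fold change of library-normalised counts.

    FC_w = ((chip_w + pc) / chip_library) / ((input_w + pc) / input_library).
    With a positive pseudocount the result is finite everywhere.
    """
    if chip.grid.windows != input_track.grid.windows:
        raise ValueError("ChIP and Input tracks are on different grids")
    num = (chip.counts + pseudocount) / chip.library_size
    den = (input_track.counts + pseudocount) / input_track.library_size
    return num / den


def call_enrichment_domains(
    fc: np.ndarray,
    track: CoverageTrack,
    threshold: float = 4.0,
    min_width: int = 50_000,
    merge_gap: int = 100_000,
    sample: str = "",
) -> List[EnrichmentDomain]:
    """Call domains as maximal runs of bins with FC > ``threshold``.

    Runs separated by <= ``merge_gap`` bp are merged; merged domains
    narrower than ``min_width`` bp are dropped.  Reported bounds are the
    outermost bounds of the constituent above-threshold bins.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    fc = np.asarray(fc, dtype=float)
    windows = track.grid.windows
    if fc.shape != (len(windows),):
        raise ValueError("fc length does not match grid")
    above = [w for w, f in zip(windows, fc) if f > threshold]
    # merge runs separated by <= merge_gap by extending each bin by gap/2
    merged = merge(
        [GenomicInterval(w.chrom, max(0, w.start - merge_gap // 2), w.end + merge_gap // 2) for w in above]
    )
    domains: List[EnrichmentDomain] = []
    for iv in merged:
        members = [
            (w, f)
            for w, f in zip(windows, fc)
            if f > threshold and w.chrom == iv.chrom and w.start >= iv.start and w.end <= iv.end
        ]
        start = min(w.start for w, _ in members)
        end = max(w.end for w, _ in members)
        if end - start < min_width:
            continue
        fcs = [f for _, f in members]
        domains.append(
            EnrichmentDomain(
                interval=GenomicInterval(iv.chrom, start, end, name=sample or None),
                mean_fc=float(np.mean(fcs)),
                peak_fc=float(np.max(fcs)),
                n_bins=len(members),
                sample=sample,
            )
        )
    return domains


def compare_domains(
    parent: EnrichmentDomain,
    derived: EnrichmentDomain,
    left_is_short_arm: bool = True,
    direction_threshold: float = 0.8,
) -> DomainComparison:
    """Compare a parent domain with its derived counterpart.

    Lost bp is split by which side of the retained core it falls on and
    labelled by arm orientation (``left_is_short_arm``: lower coordinates
    are the short-arm direction).  The direction label names an arm when
    >= ``direction_threshold`` of the lost bp lies on that one side.
    """
    if parent.interval.chrom != derived.interval.chrom:
        raise ValueError("domains on different chromosomes")
    p, d = parent.interval, derived.interval
    core = intersect([p], [d])
    retained_bp = total_length(core)
    lost_left = lost_right = 0
    if retained_bp == 0:
        lost_left = p.width  # no overlap: all of parent lost, direction "both"
        lost_right = 0
    else:
        lost_left = max(0, core[0].start - p.start)
        lost_right = max(0, p.end - core[-1].end)
    lost_total = lost_left + lost_right
    if retained_bp == 0:
        direction = "both"
    elif lost_total == 0:
        direction = "none"
    elif lost_left >= direction_threshold * lost_total:
        direction = "short-arm" if left_is_short_arm else "long-arm"
    elif lost_right >= direction_threshold * lost_total:
        direction = "long-arm" if left_is_short_arm else "short-arm"
    else:
        direction = "both"
    lost_short = lost_left if left_is_short_arm else lost_right
    lost_long = lost_right if left_is_short_arm else lost_left
    return DomainComparison(
        parent=parent,
        derived=derived,
        size_delta=p.width - d.width,
        retained_bp=retained_bp,
        retained_fraction=retained_bp / p.width,
        lost_short_arm_bp=lost_short,
        lost_long_arm_bp=lost_long,
        direction=direction,
    )


def partition_variable_stable(
    parent: EnrichmentDomain, derived: Sequence[EnrichmentDomain]
) -> CentromerePartition:
    """Partition the parent centromere into R1 (variable) and R2 (stable).

    R2 is the part of the parent domain where CENH3 binding is retained in
    every derived line (intersection of all derived domains with the
    parent); R1 is the remainder.  By construction R1 and R2 are disjoint
    and their union is the parent domain.
    """
    if not derived:
        raise ValueError("need at least one derived domain")
    import logging

    r2 = [parent.interval]
    for dom in derived:
        r2 = intersect(r2, [dom.interval])
    if not r2:
        logging.getLogger(__name__).warning(
            "no region retained in all derived lines; R2 empty, R1 = parent"
        )
    r1 = subtract([parent.interval], r2)
    return CentromerePartition(r1=r1, r2=r2)
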