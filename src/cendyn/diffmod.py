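"""Differential statistics for histone-modification and accessibility tracks.

Region-level intensities are read counts divided by library size; region
fold changes are tested with Fisher's exact test on read counts vs library
totals.  Window-level differential modification windows (DMWs) are called
from replicated counts with an exact-style negative-binomial test using a
method-of-moments common dispersion (degenerating to the conditional
binomial/Fisher test when replicates show no overdispersion), BH-adjusted,
at fold change > 1.5 and adjusted p < 0.05.  Pericentromere profiles,
arm-symmetry rank tests and accessibility/modification change correlations
complete the window analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval
from .windows import CoverageTrack, WindowGrid

__all__ = [
    "IntensityRecord",
    "DMW",
    "PericentromereProfile",
    "region_intensity",
    "region_fold_change_test",
    "estimate_common_dispersion",
    "call_dmws",
    "pericentromere_profile",
    "arm_symmetry_test",
    "change_correlation",
]


@dataclass(frozen=True)
class IntensityRecord:
    """Library-normalised read intensity of one region in one track."""

    region: GenomicInterval
    sample: str
    mark: str
    raw_count: float
    library_size: float

    @property
    def normalized(self) -> float:
        return self.raw_count / self.library_size


@dataclass(frozen=True)
class DMW:
    """A differential modification window."""

    window: GenomicInterval
    mark: str
    contrast: str
    log2_fc: float
    p_value: float
    adj_p: float

    @property
    def direction(self) -> str:
        return "up" if self.log2_fc > 0 else "down"


@dataclass
class PericentromereProfile:
    """Per-box intensities across the flanks of a centromere.

    Boxes are ordered by signed distance from the centromere edge: negative
    indices on the left (lower-coordinate) side, positive on the right.
    """

    centromere: GenomicInterval
    sample: str
    mark: str
    box_indices: List[int]
    boxes: List[GenomicInterval]
    intensities: List[float]
    clipped: bool  # true when a chromosome end truncated the flank


def region_intensity(track: CoverageTrack, region: GenomicInterval) -> IntensityRecord:
    """Sum counts of windows whose midpoint lies in ``region``, over library size."""
    if region.width <= 0:
        raise ValueError("empty region")
    mids = track.grid.midpoints()
    chroms = np.array([w.chrom for w in track.grid.windows])
    inside = (chroms == region.chrom) & (mids >= region.start) & (mids < region.end)
    return IntensityRecord(
        region=region,
        sample=track.sample,
        mark=track.mark,
        raw_count=float(track.counts[inside].sum()),
        library_size=track.library_size,
    )


def region_fold_change_test(
    a: IntensityRecord, b: IntensityRecord, pseudocount: float = 0.5
) -> Tuple[float, float]:
    """Fold change of normalised intensities (a over b) with Fisher's exact p.

    The 2x2 table is [[count_a, library_a - count_a],
    [count_b, library_b - count_b]], two-sided.  The pseudocount only
    guards the fold change when a raw count is zero.
    """
    if a.library_size <= 0 or b.library_size <= 0:
        raise ValueError("library sizes must be > 0")
    ra, rb = a.raw_count, b.raw_count
    if ra == 0 or rb == 0:
        fc = ((ra + pseudocount) / a.library_size) / ((rb + pseudocount) / b.library_size)
    else:
        fc = a.normalized / b.normalized
    table = [
        [int(round(ra)), int(round(a.library_size - ra))],
        [int(round(rb)), int(round(b.library_size - rb))],
    ]
    p = stats.fisher_exact(table, alternative="two-sided")[1]
    return float(fc), float(p)


def estimate_common_dispersion(
    groups: Sequence[Sequence[CoverageTrack]],
) -> float:
    """Method-of-moments common NB dispersion across replicate groups.

    Counts are scaled to each group's mean library size; with var(count) =
    mu + phi mu^2, phi is estimated by pooling moments over all windows:
    sum(var_w - mean_w) / sum(mean_w^2 - var_w / n_rep) (the denominator
    correction removes the bias of mean_w^2 as an estimate of mu_w^2).
    Floored at 0; groups with a single replicate contribute nothing.
    """
    num = den = 0.0
    for tracks in groups:
        if len(tracks) < 2:
            continue
        libs = np.array([t.library_size for t in tracks])
        ref = libs.mean()
        scaled = np.stack([t.counts * (ref / t.library_size) for t in tracks])
        mean = scaled.mean(axis=0)
        var = scaled.var(axis=0, ddof=1)
        ok = mean > 0
        num += float((var[ok] - mean[ok]).sum())
        den += float((mean[ok] ** 2 - var[ok] / len(tracks)).sum())
    if den <= 0:
        return 0.0
    return float(max(0.0, num / den))


def _nb_exact_pvalues(
    a: np.ndarray, b: np.ndarray, lib_a: float, lib_b: float, phi: float
) -> np.ndarray:
    """Exact-style two-sided test of pooled counts a vs b.

    Conditions on s = a + b and sums the probabilities of all splits no more
    likely than the observed one, with split probabilities from independent
    NB (Poisson when phi = 0) distributions with means proportional to the
    library sizes under the null.
    """
    n = len(a)
    pvals = np.ones(n)
    rate = (a + b) / (lib_a + lib_b)
    for i in range(n):
        s = int(a[i] + b[i])
        if s == 0:
            continue
        ks = np.arange(s + 1)
        mu_a, mu_b = rate[i] * lib_a, rate[i] * lib_b
        if phi > 0:
            r = 1.0 / phi
            la = stats.nbinom.logpmf(ks, r, r / (r + mu_a))
            lb = stats.nbinom.logpmf(ks[::-1], r, r / (r + mu_b))
        else:
            la = stats.poisson.logpmf(ks, mu_a)
            lb = stats.poisson.logpmf(ks[::-1], mu_b)
        logp = la + lb
        logp -= logp.max()
        probs = np.exp(logp)
        probs /= probs.sum()
        obs = probs[int(a[i])]
        pvals[i] = min(1.0, probs[probs <= obs * (1 + 1e-12)].sum())
    return pvals


def call_dmws(
    parent: Sequence[CoverageTrack],
    derived: Sequence[CoverageTrack],
    grid: Optional[WindowGrid] = None,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
    mark: str = "",
    contrast: str = "derived_vs_parent",
) -> List[DMW]:
    """Call differential modification windows (derived vs parent).

    Replicates are pooled per condition; each window is tested with the
    exact-style NB test (common dispersion estimated from replicates by
    method of moments, scaled for pooling) and BH-adjusted across all
    windows of the contrast.  A window is a DMW iff its fold change of
    library-normalised mean counts (pseudocount 0.5) exceeds
    ``fc_threshold`` in either direction and adjusted p < ``alpha``.
    """
    if not parent or not derived:
        raise ValueError("need >= 1 replicate per condition")
    grid = grid or parent[0].grid
    for t in list(parent) + list(derived):
        if t.grid.windows != grid.windows:
            raise ValueError("track grid mismatch")
    mark = mark or parent[0].mark
    pa = np.sum([t.counts for t in parent], axis=0)
    pd_ = np.sum([t.counts for t in derived], axis=0)
    lib_a = float(sum(t.library_size for t in parent))
    lib_b = float(sum(t.library_size for t in derived))
    # normalised mean fold change, derived over parent
    norm_a = np.mean([t.counts / t.library_size for t in parent], axis=0)
    norm_b = np.mean([t.counts / t.library_size for t in derived], axis=0)
    ref = (lib_a + lib_b) / (len(parent) + len(derived))
    fc = (norm_b * ref + pseudocount) / (norm_a * ref + pseudocount)
    phi = estimate_common_dispersion([parent, derived])
    # sum of r NB(mu, phi) draws is NB(r mu, phi / r): pooling divides dispersion
    phi_pooled = phi / min(len(parent), len(derived))
    pvals = _nb_exact_pvalues(pd_, pa, lib_b, lib_a, phi_pooled)
    adj = multipletests(pvals, method="fdr_bh")[1]
    out: List[DMW] = []
    for w, f, p, q in zip(grid.windows, fc, pvals, adj):
        if q < alpha and (f > fc_threshold or f < 1.0 / fc_threshold):
            out.append(
                DMW(window=w, mark=mark, contrast=contrast,
                    log2_fc=float(np.log2(f)), p_value=float(p), adj_p=float(q))
            )
    return out


def pericentromere_profile(
    track: CoverageTrack,
    centromere: GenomicInterval,
    flank: int = 5_000_000,
    box: int = 1_000_000,
) -> PericentromereProfile:
    """Normalised intensity in 1-Mb boxes across the centromere flanks.

    ``flank // box`` boxes per side, clipped (and flagged) at chromosome
    ends; box index -k is the k-th box left of the centromere start, +k the
    k-th box right of the end.
    """
    chrom_len = track.grid.chrom_sizes[centromere.chrom]
    n_boxes = flank // box
    indices: List[int] = []
    boxes: List[GenomicInterval] = []
    clipped = False
    for k in range(n_boxes, 0, -1):
        start = centromere.start - k * box
        end = centromere.start - (k - 1) * box
        if end <= 0:
            clipped = True
            continue
        if start < 0:
            clipped = True
            start = 0
        indices.append(-k)
        boxes.append(GenomicInterval(centromere.chrom, start, end))
    for k in range(1, n_boxes + 1):
        start = centromere.end + (k - 1) * box
        end = centromere.end + k * box
        if start >= chrom_len:
            clipped = True
            continue
        if end > chrom_len:
            clipped = True
            end = chrom_len
        indices.append(k)
        boxes.append(GenomicInterval(centromere.chrom, start, end))
    intensities = [region_intensity(track, b).normalized for b in boxes]
    return PericentromereProfile(
        centromere=centromere, sample=track.sample, mark=track.mark,
        box_indices=indices, boxes=boxes, intensities=intensities, clipped=clipped,
    )


def arm_symmetry_test(
    changes_long: Sequence[float], changes_short: Sequence[float]
) -> Tuple[float, Optional[float]]:
    """Two-sided rank-sum test of per-window change values between arms.

    Returns (U statistic, p).  With fewer than 3 windows on a side the p is
    reported unavailable (None) with a warning; fully tied inputs give p = 1.
    """
    import logging

    x = np.asarray(changes_long, dtype=float)
    y = np.asarray(changes_short, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both sides must be non-empty")
    if len(x) < 3 or len(y) < 3:
        logging.getLogger(__name__).warning(
            "a side has < 3 windows (%d, %d): p unavailable", len(x), len(y)
        )
        return float("nan"), None
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return float(len(x) * len(y) / 2), 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def change_correlation(
    delta_a: Sequence[float], delta_b: Sequence[float]
) -> Tuple[float, float]:
    """Pearson correlation (r, two-sided p) of two per-window change vectors."""
    x = np.asarray(delta_a, dtype=float)
    y = np.asarray(delta_b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("change vectors differ in length")
    if len(x) < 3:
        raise ValueError("need >= 3 windows")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
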