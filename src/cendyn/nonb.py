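"""Non-B-form DNA motif scanning, density, enrichment and stability scores.

Seven motif classes are recognised, each defined by an explicit sequence
rule (scanners report maximal, left-greedy, non-redundant hits):

APR  A-phased repeats: >= 3 A-tracts (3-9 consecutive A's or T's, not mixed
     within a tract, taken as maximal homopolymer runs), consecutive tracts
     separated by 4-9 bp spacers so tracts share helical phasing.
DR   Direct repeats: a 10-50 bp unit repeated in tandem (exact match),
     maximal periodic span >= 2 units; the unit must contain >= 2 distinct
     bases (homopolymer-degenerate repeats are STRs, not DRs).
GQ   G-quadruplex: >= 4 maximal runs of >= 3 G's with 1-7 bp loops
     (both strands; C-run pattern reported on '-').
IR   Inverted repeats: arms >= 10 bp, reverse-complement match, loop <= 100 bp.
MR   Mirror repeats: arms >= 10 bp, reversed (not complemented) match,
     loop <= 100 bp; arms must contain >= 2 distinct bases (a homopolymer
     is trivially its own mirror image).
STR  Short tandem repeats: unit 1-9 bp, maximal periodic span >= 20 bp
     (>= 9 bp for mononucleotide runs).
Z    Z-DNA: alternating purine/pyrimidine of GC/CA/GT dinucleotide steps,
     length >= 12 bp.

N bases never match any rule.  Windowed DNA duplex stability is scored with
unified nearest-neighbour dinucleotide free energies (kcal/mol, 37 C; more
negative = more stable) over 300-nt windows stepped by 150 nt, with a hook
for reading externally computed folding energies instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, merge
from .io import SequenceRecord
from .windows import WindowGrid

__all__ = [
    "MotifHit",
    "EnergyWindow",
    "MOTIF_CLASSES",
    "scan_motifs",
    "motif_density",
    "permutation_enrichment",
    "window_free_energy",
    "compare_region_energy",
]

MOTIF_CLASSES = ("APR", "DR", "GQ", "IR", "MR", "STR", "Z")

_COMP = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class MotifHit:
    """One non-B motif occurrence."""

    motif_class: str
    interval: GenomicInterval
    matched: str
    strand: str = "+"
    attrs: Dict[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.motif_class not in MOTIF_CLASSES:
            raise ValueError(f"unknown motif class {self.motif_class!r}")
        if len(self.matched) != self.interval.width:
            raise ValueError("matched subsequence length != interval width")


@dataclass(frozen=True)
class EnergyWindow:
    """Windowed duplex stability score in kcal/mol."""

    interval: GenomicInterval
    score: float


def _runs_of(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Half-open [start, end) spans of True runs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return list(zip(starts.tolist(), ends.tolist()))


def _drop_contained(spans: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Remove spans contained in another span; keep left-greedy order."""
    spans = sorted(set(spans))
    out: List[Tuple[int, int]] = []
    max_end = -1
    for s, e in spans:
        if e <= max_end:
            continue
        # a later span can't contain an earlier one after sorting unless same start
        while out and out[-1][0] == s:
            out.pop()
        out.append((s, e))
        max_end = e
    return out


# ---------------------------------------------------------------------------
# per-class scanners
# ---------------------------------------------------------------------------

def _tracts(seq: str, min_len: int, max_len: int) -> List[Tuple[int, int]]:
    """Maximal homopolymer A- or T-runs with length in [min_len, max_len]."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out: List[Tuple[int, int]] = []
    for base in (ord("A"), ord("T")):
        for s, e in _runs_of(arr == base):
            if min_len <= e - s <= max_len:
                out.append((s, e))
    return sorted(out)


def _scan_apr(seq: str, params: Dict) -> List[Tuple[int, int, Dict]]:
    min_tracts = params.get("min_tracts", 3)
    tmin, tmax = params.get("tract_min", 3), params.get("tract_max", 9)
    smin, smax = params.get("spacer_min", 4), params.get("spacer_max", 9)
    tracts = _tracts(seq, tmin, tmax)
    hits = []
    i = 0
    while i < len(tracts):
        j = i
        while j + 1 < len(tracts) and smin <= tracts[j + 1][0] - tracts[j][1] <= smax:
            j += 1
        if j - i + 1 >= min_tracts:
            hits.append((tracts[i][0], tracts[j][1], {"n_tracts": j - i + 1}))
        i = j + 1
    return hits


def _chain_runs(
    runs: List[Tuple[int, int]], min_runs: int, gap_min: int, gap_max: int
) -> List[Tuple[int, int, Dict]]:
    hits = []
    i = 0
    while i < len(runs):
        j = i
        while j + 1 < len(runs) and gap_min <= runs[j + 1][0] - runs[j][1] <= gap_max:
            j += 1
        if j - i + 1 >= min_runs:
            hits.append((runs[i][0], runs[j][1], {"n_tracts": j - i + 1}))
        i = j + 1
    return hits


def _scan_gq(seq: str, params: Dict) -> List[Tuple[int, int, Dict, str]]:
    min_run = params.get("g_run", 3)
    min_runs = params.get("min_runs", 4)
    lmin, lmax = params.get("loop_min", 1), params.get("loop_max", 7)
    both = params.get("both_strands", True)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = []
    strands = [("G", "+")] + ([("C", "-")] if both else [])
    for base, strand in strands:
        runs = [(s, e) for s, e in _runs_of(arr == ord(base)) if e - s >= min_run]
        for s, e, attrs in _chain_runs(runs, min_runs, lmin, lmax):
            out.append((s, e, attrs, strand))
    return sorted(out)


def _periodic_hits(
    seq: str, unit_min: int, unit_max: int, min_span, mixed_unit: bool = False
) -> List[Tuple[int, int, Dict]]:
    """Maximal intervals with periodicity u in [unit_min, unit_max].

    ``min_span`` is an int or a callable unit -> minimum total span;
    ``mixed_unit`` additionally requires the repeat unit to contain at
    least two distinct bases.  Contained intervals are dropped across units
    (smallest unit wins ties).
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(arr)
    best: Dict[Tuple[int, int], int] = {}
    for u in range(unit_min, min(unit_max, n - 1) + 1):
        need = min_span(u) if callable(min_span) else min_span
        eq = (arr[:-u] == arr[u:]) & (arr[:-u] != ord("N"))
        for s, e in _runs_of(eq):
            span = (s, e + u)  # periodic region includes the trailing unit
            if span[1] - span[0] < max(need, 2 * u):
                continue
            if mixed_unit and len(set(seq[s : s + u])) < 2:
                continue
            if span not in best or u < best[span]:
                best[span] = u
    spans = _drop_contained(list(best))
    return [(s, e, {"unit": best[(s, e)], "n_units": (e - s) // best[(s, e)]}) for s, e in spans]


def _scan_z(seq: str, params: Dict) -> List[Tuple[int, int, Dict]]:
    min_len = params.get("min_length", 12)
    allowed = {"GC", "CG", "CA", "AC", "GT", "TG"}
    ok = np.array([seq[i : i + 2] in allowed for i in range(len(seq) - 1)], dtype=bool)
    hits = []
    for s, e in _runs_of(ok):
        if e + 1 - s >= min_len:  # run of k allowed steps spans k+1 bases
            hits.append((s, e + 1, {}))
    return hits


def _seed_pairs(seq: str, k: int, max_gap: int, mirror: bool) -> List[Tuple[int, int]]:
    """(end-of-left-arm, start-of-right-arm) candidate innermost pairs from
    exact k-mer seeds with gap <= max_gap + 2k (seeds may sit anywhere in
    the innermost k bp of each arm, so gap slack covers them)."""
    index: Dict[str, List[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    pairs = set()
    for j in range(len(seq) - k + 1):
        right = seq[j : j + k]
        if "N" in right:
            continue
        target = right[::-1] if mirror else right.translate(_COMP)[::-1]
        for i in index.get(target, []):
            # left arm k-mer ends at i+k-1, right arm k-mer starts at j
            if 0 <= j - (i + k) <= max_gap:
                pairs.add((i + k - 1, j))
    return sorted(pairs)


def _scan_palindromic(seq: str, params: Dict, mirror: bool) -> List[Tuple[int, int, Dict]]:
    min_arm = params.get("min_arm", 10)
    max_loop = params.get("max_loop", 100)
    n = len(seq)
    match = (lambda a, b: a == b and a != "N") if mirror else (
        lambda a, b: a != "N" and b != "N" and a == b.translate(_COMP)
    )
    seen = set()
    raw: List[Tuple[int, int, Dict]] = []
    for u, v in _seed_pairs(seq, min_arm, max_loop, mirror):
        # extend inward to the true innermost matching pair
        while v - u - 1 >= 2 and match(seq[u + 1], seq[v - 1]):
            u, v = u + 1, v - 1
        key = (u, v)
        if key in seen:
            continue
        seen.add(key)
        loop = v - u - 1
        if loop > max_loop:
            continue
        # extend outward to maximal arms
        a = 0
        while u - a >= 0 and v + a < n and match(seq[u - a], seq[v + a]):
            a += 1
        if a < min_arm:
            continue
        if mirror and len(set(seq[u - a + 1 : u + 1])) < 2:
            continue  # homopolymer arm: trivially mirror-symmetric
        raw.append((u - a + 1, v + a, {"arm": a, "loop": loop}))
    spans = _drop_contained([(s, e) for s, e, _ in raw])
    attrs = {(s, e): d for s, e, d in raw}
    return [(s, e, attrs[(s, e)]) for s, e in spans]


def scan_motifs(
    seq: SequenceRecord, motif_class: str, params: Optional[Dict] = None
) -> List[MotifHit]:
    """Scan a sequence for one motif class; hits are maximal, left-greedy
    and non-redundant (no hit contained in another of the same class)."""
    params = params or {}
    s = seq.sequence
    if motif_class == "APR":
        found = [(a, b, d, "+") for a, b, d in _scan_apr(s, params)]
    elif motif_class == "GQ":
        found = _scan_gq(s, params)
    elif motif_class == "DR":
        found = [
            (a, b, d, "+")
            for a, b, d in _periodic_hits(
                s, params.get("unit_min", 10), params.get("unit_max", 50),
                params.get("min_span", 0), mixed_unit=True,
            )
        ]
    elif motif_class == "STR":
        min_span = lambda u: params.get("mono_min", 9) if u == 1 else params.get("min_span", 20)
        found = [
            (a, b, d, "+")
            for a, b, d in _periodic_hits(
                s, params.get("unit_min", 1), params.get("unit_max", 9), min_span
            )
        ]
    elif motif_class == "IR":
        found = [(a, b, d, "+") for a, b, d in _scan_palindromic(s, params, mirror=False)]
    elif motif_class == "MR":
        found = [(a, b, d, "+") for a, b, d in _scan_palindromic(s, params, mirror=True)]
    elif motif_class == "Z":
        found = [(a, b, d, "+") for a, b, d in _scan_z(s, params)]
    else:
        raise ValueError(f"unknown motif class {motif_class!r}")
    return [
        MotifHit(
            motif_class=motif_class,
            interval=GenomicInterval(seq.id, a, b, name=motif_class),
            matched=s[a:b],
            strand=strand,
            attrs=attrs,
        )
        for a, b, attrs, strand in sorted(found)
    ]


# ---------------------------------------------------------------------------
# density and enrichment
# ---------------------------------------------------------------------------

def motif_density(hits: Sequence[MotifHit], grid: WindowGrid) -> pd.DataFrame:
    """Per-window hit count (by midpoint) and bp-coverage fraction
    (overlapping hits merged first so no base is counted twice)."""
    counts = np.zeros(grid.n_windows)
    coverage_bp = np.zeros(grid.n_windows)
    for h in hits:
        mid = (h.interval.start + h.interval.end) // 2
        idx = grid.window_index(h.interval.chrom, mid)
        if idx is not None:
            counts[idx] += 1
    merged = merge([h.interval for h in hits])
    for iv in merged:
        for w_idx, w in enumerate(grid.windows):
            if w.chrom == iv.chrom and iv.start < w.end and w.start < iv.end:
                coverage_bp[w_idx] += min(iv.end, w.end) - max(iv.start, w.start)
    rows = [
        {
            "chrom": w.chrom, "start": w.start, "end": w.end,
            "count": counts[i], "coverage": coverage_bp[i] / w.width,
        }
        for i, w in enumerate(grid.windows)
    ]
    return pd.DataFrame(rows)


def permutation_enrichment(
    densities: Sequence[float],
    cen_windows: Sequence[int],
    n_perm: int = 1000,
    seed: int = 0,
) -> Tuple[float, float]:
    """One-sided permutation test: is mean density over centromeric windows
    higher than over randomly drawn non-centromeric window sets?

    p = (1 + #{null mean >= observed}) / (n_perm + 1).
    """
    dens = np.asarray(densities, dtype=float)
    cen = np.asarray(sorted(set(cen_windows)), dtype=int)
    if len(cen) < 1:
        raise ValueError("need >= 1 centromeric window")
    pool = np.setdiff1d(np.arange(len(dens)), cen)
    if len(pool) <= len(cen):
        raise ValueError("non-centromeric pool must be larger than the centromeric set")
    observed = dens[cen].mean()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xBEEF)))
    null = np.array(
        [dens[rng.choice(pool, size=len(cen), replace=False)].mean() for _ in range(n_perm)]
    )
    p = (1 + int((null >= observed - 1e-12).sum())) / (n_perm + 1)
    return float(observed), float(p)


# ---------------------------------------------------------------------------
# windowed stability scores
# ---------------------------------------------------------------------------

# unified nearest-neighbour duplex free energies, kcal/mol at 37 C
NN_DG37: Dict[str, float] = {
    "AA": -1.00, "TT": -1.00, "AT": -0.88, "TA": -0.58,
    "CA": -1.45, "TG": -1.45, "GT": -1.44, "AC": -1.44,
    "CT": -1.28, "AG": -1.28, "GA": -1.30, "TC": -1.30,
    "CG": -2.17, "GC": -2.24, "GG": -1.84, "CC": -1.84,
}
NN_INITIATION = 1.96


def _nn_score(window: str) -> float:
    return NN_INITIATION + sum(NN_DG37.get(window[i : i + 2], 0.0) for i in range(len(window) - 1))


def window_free_energy(
    seq: SequenceRecord,
    width: int = 300,
    step: int = 150,
    engine: str = "nn-duplex",
    external_scores: Optional[pd.DataFrame] = None,
) -> List[EnergyWindow]:
    """Stability score per sliding window (default 300 nt stepped by 150).

    ``nn-duplex`` sums unified nearest-neighbour stack energies plus
    initiation per window; ``external`` takes precomputed scores from a
    table with columns (chrom, start, end, score), enabling drop-in use of a
    folding program's output.
    """
    if width <= 0 or not 0 < step <= width:
        raise ValueError("require width > 0 and 0 < step <= width")
    if engine == "external":
        if external_scores is None:
            raise ValueError("external engine requires external_scores")
        return [
            EnergyWindow(GenomicInterval(r.chrom, int(r.start), int(r.end)), float(r.score))
            for r in external_scores.itertuples()
            if r.chrom == seq.id
        ]
    if engine != "nn-duplex":
        raise ValueError(f"unknown engine {engine!r}")
    out = []
    pos = 0
    n = len(seq.sequence)
    while pos < n:
        end = min(pos + width, n)
        if end - pos >= 2:
            out.append(EnergyWindow(GenomicInterval(seq.id, pos, end), _nn_score(seq.sequence[pos:end])))
        if end == n:
            break
        pos += step
    return out


def compare_region_energy(
    windows: Sequence[EnergyWindow],
    regions: Dict[str, Sequence[GenomicInterval]],
) -> pd.DataFrame:
    """Per-region mean/median stability with pairwise two-sided rank-sum
    p-values; windows are assigned to regions by midpoint."""
    groups: Dict[str, List[float]] = {name: [] for name in regions}
    for w in windows:
        mid = (w.interval.start + w.interval.end) // 2
        for name, ivs in regions.items():
            if any(iv.chrom == w.interval.chrom and iv.start <= mid < iv.end for iv in ivs):
                groups[name].append(w.score)
    for name, vals in groups.items():
        if len(vals) < 3:
            raise ValueError(f"region {name!r} maps to {len(vals)} windows (< 3)")
    names = list(regions)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            x, y = np.array(groups[a]), np.array(groups[b])
            if len(x) == len(y) and np.array_equal(np.sort(x), np.sort(y)):
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
            rows.append(
                {"region_a": a, "region_b": b,
                 "mean_a": x.mean(), "mean_b": y.mean(),
                 "median_a": float(np.median(x)), "median_b": float(np.median(y)),
                 "n_a": len(x), "n_b": len(y), "p_value": p}
            )
    return pd.DataFrame(rows)
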