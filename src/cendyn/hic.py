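"""Hi-C contact-matrix normalisation and structure comparison.

Implements the comparative Hi-C stack: sequencing-depth normalisation and
Knight-Ruiz (KR) matrix balancing, log2 difference maps between samples,
A/B compartment assignment from the first principal component of the
observed/expected correlation matrix, insulation-score TAD calling, and
boundary comparison between samples annotated with overlapping features
(e.g. differential-modification windows).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import signal, stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval

__all__ = [
    "ContactMatrix",
    "CompartmentTrack",
    "TadSet",
    "balance_matrix",
    "difference_map",
    "compartment_pc1",
    "region_pc1_stats",
    "find_tads",
    "compare_boundaries",
    "read_contact_matrix",
    "write_contact_matrix",
]


@dataclass
class ContactMatrix:
    """Symmetric binned contact matrix for one chromosome segment.

    ``start`` is the bp coordinate of bin 0, so bin ``i`` spans
    ``[start + i * resolution, start + (i+1) * resolution)``.
    """

    counts: np.ndarray
    resolution: int
    chrom: str = "chr1"
    start: int = 0
    balancing: str = "raw"  # raw | depth | KR
    masked: Set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = self.counts.shape[0]
        if self.counts.shape != (n, n):
            raise ValueError("contact matrix must be square")
        if not np.allclose(self.counts, self.counts.T, atol=1e-8):
            raise ValueError("contact matrix must be symmetric")
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def unmasked(self) -> np.ndarray:
        keep = np.ones(self.n_bins, dtype=bool)
        keep[list(self.masked)] = False
        return keep

    def bin_range(self, region: GenomicInterval) -> np.ndarray:
        """Indices of bins whose midpoint falls inside ``region``."""
        if region.chrom != self.chrom:
            return np.array([], dtype=int)
        mids = self.start + (np.arange(self.n_bins) + 0.5) * self.resolution
        return np.nonzero((mids >= region.start) & (mids < region.end))[0]

    def bin_interval(self, i: int) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.start + i * self.resolution, self.start + (i + 1) * self.resolution
        )


def read_contact_matrix(path, resolution: int, chrom: str = "chr1", start: int = 0) -> ContactMatrix:
    """Read a triplet TSV (bin_i, bin_j, count) into a dense symmetric matrix."""
    df = pd.read_csv(path, sep="\t", header=None, names=["i", "j", "count"], comment="#")
    n = int(max(df["i"].max(), df["j"].max())) + 1
    m = np.zeros((n, n))
    m[df["i"], df["j"]] = df["count"]
    m = np.triu(m) + np.triu(m, 1).T if np.allclose(m, np.triu(m)) else np.maximum(m, m.T)
    return ContactMatrix(m, resolution=resolution, chrom=chrom, start=start)


def write_contact_matrix(m: ContactMatrix, path) -> None:
    """Write the upper triangle as triplet TSV (bin_i, bin_j, count)."""
    iu = np.triu_indices(m.n_bins)
    nz = m.counts[iu] != 0
    pd.DataFrame(
        {"i": iu[0][nz], "j": iu[1][nz], "count": m.counts[iu][nz]}
    ).to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# balancing
# ---------------------------------------------------------------------------

def _kr_scaling(a: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """Knight-Ruiz balancing vector x with diag(x) a diag(x) doubly stochastic.

    Inexact-Newton inner conjugate-gradient iteration following the published
    algorithm; raises on non-convergence.
    """
    n = a.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, big_delta = 0.1, 3.0
    g, etamax = 0.9, 0.1
    eta = etamax
    stop_tol = tol * 0.5
    rt = tol**2
    v = x * (a @ x)
    rk = 1 - v
    rho_km1 = rk @ rk
    rout = rold = rho_km1
    n_outer = 0
    mvp = 0
    while rout > rt:
        n_outer += 1
        if n_outer > max_iter:
            raise RuntimeError(
                f"KR balancing did not converge: residual {np.sqrt(rout):.3e} after "
                f"{n_outer - 1} outer iterations ({mvp} matvecs)"
            )
        k = 0
        y = e.copy()
        innertol = max(eta**2 * rout, rt)
        rho_km2 = rho_km1
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            if k > max_iter:
                raise RuntimeError("KR inner CG iteration exceeded max_iter")
            w = x * (a @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                neg = ap < 0
                gamma = ((delta - y[neg]) / ap[neg]).min()
                y += gamma * ap
                break
            if ynew.max() >= big_delta:
                ind = ynew > big_delta
                gamma = ((big_delta - y[ind]) / ap[ind]).min()
                y += gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
        x = x * y
        v = x * (a @ x)
        rk = 1 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        mvp += k + 1
        rat = rout / rold
        rold = rout
        eta_o = eta
        eta = g * rat
        if g * eta_o**2 > 0.1:
            eta = max(eta, g * eta_o**2)
        eta = max(min(eta, etamax), stop_tol / np.sqrt(rout))
    return x


def balance_matrix(
    m: ContactMatrix, method: str = "KR", tol: float = 1e-6, max_iter: int = 3000
) -> ContactMatrix:
    """Depth-normalise or KR-balance a contact matrix.

    ``depth``: counts per million total contacts.  ``KR``: Knight-Ruiz
    scaling so all unmasked row sums are equal (coefficient of variation
    below ``tol``); the total is rescaled to the input total.  Bins with zero
    marginal are masked first and left zero.
    """
    if method not in ("depth", "KR"):
        raise ValueError(f"unknown balancing method {method!r}")
    if method == "depth":
        total = m.counts.sum()
        if total == 0:
            raise ValueError("empty matrix")
        return replace(m, counts=m.counts * (1e6 / total), balancing="depth")
    if m.balancing == "KR":
        raise ValueError("matrix already KR-balanced")
    marginal = m.counts.sum(axis=1)
    masked = set(m.masked) | set(np.nonzero(marginal == 0)[0])
    keep = np.ones(m.n_bins, dtype=bool)
    keep[list(masked)] = False
    sub = m.counts[np.ix_(keep, keep)]
    x = _kr_scaling(sub, tol=tol, max_iter=max_iter)
    balanced_sub = (x[:, None] * sub) * x[None, :]
    balanced_sub *= sub.sum() / balanced_sub.sum()  # preserve total
    out = np.zeros_like(m.counts)
    out[np.ix_(keep, keep)] = balanced_sub
    return replace(m, counts=out, balancing="KR", masked=masked)


def difference_map(a: ContactMatrix, b: ContactMatrix, pseudocount: float = 1e-6) -> np.ndarray:
    """log2((a + pc) / (b + pc)); antisymmetric under operand swap."""
    if a.counts.shape != b.counts.shape:
        raise ValueError("contact matrices differ in shape")
    if a.resolution != b.resolution or a.chrom != b.chrom:
        raise ValueError("contact matrices differ in segment/resolution")
    # log difference (not log-of-ratio) so diff(a, b) == -diff(b, a) exactly
    return np.log2(a.counts + pseudocount) - np.log2(b.counts + pseudocount)


# ---------------------------------------------------------------------------
# compartments
# ---------------------------------------------------------------------------

@dataclass
class CompartmentTrack:
    """Per-bin PC1 with A/B labels (A: PC1 > 0, B: PC1 < 0)."""

    matrix: ContactMatrix
    pc1: np.ndarray  # nan on masked bins
    labels: np.ndarray  # 'A' / 'B' / '' on masked
    orientation_anchor: str = "orientation_track"


def _observed_expected(sub: np.ndarray) -> np.ndarray:
    n = sub.shape[0]
    oe = np.zeros_like(sub)
    for d in range(n):
        diag = np.diagonal(sub, d)
        mean = diag.mean()
        if mean > 0:
            vals = diag / mean
            idx = np.arange(n - d)
            oe[idx, idx + d] = vals
            oe[idx + d, idx] = vals
    return oe


def compartment_pc1(
    m: ContactMatrix, orientation_track: Optional[np.ndarray] = None
) -> CompartmentTrack:
    """A/B compartments from PC1 of the observed/expected correlation matrix.

    The matrix must be balanced.  PC1's global sign is arbitrary, so it is
    oriented to correlate positively with ``orientation_track`` (typically
    gene density, making A the gene-rich state); without a track the sign is
    left as computed.
    """
    if m.balancing == "raw":
        raise ValueError("balance the matrix before compartment calling")
    keep = m.unmasked()
    marginal = m.counts.sum(axis=1)
    keep &= marginal > 0
    if keep.sum() < 20:
        raise ValueError("need >= 20 unmasked bins for PC1")
    sub = m.counts[np.ix_(keep, keep)]
    oe = _observed_expected(sub)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(oe)
    corr = np.nan_to_num(corr)
    if not np.any(corr):
        raise ValueError("degenerate correlation matrix")
    # first principal component of the correlation matrix
    centered = corr - corr.mean(axis=0, keepdims=True)
    cov = centered.T @ centered
    w, vec = np.linalg.eigh(cov)
    pc = centered @ vec[:, -1]
    pc1 = np.full(m.n_bins, np.nan)
    pc1[keep] = pc
    anchor = "none"
    if orientation_track is not None:
        anchor = "orientation_track"
        track = np.asarray(orientation_track, dtype=float)
        if track.shape != (m.n_bins,):
            raise ValueError("orientation_track length mismatch")
        r = np.corrcoef(pc, track[keep])[0, 1]
        if np.isfinite(r) and r < 0:
            pc1 = -pc1
    labels = np.where(np.isnan(pc1), "", np.where(pc1 > 0, "A", "B"))
    return CompartmentTrack(matrix=m, pc1=pc1, labels=labels, orientation_anchor=anchor)


def region_pc1_stats(
    track: CompartmentTrack,
    regions: Dict[str, GenomicInterval],
    other: CompartmentTrack,
) -> pd.DataFrame:
    """Mean PC1 per region for two samples, with the fold change of
    magnitudes (|other| / |self|, 2 decimals) and a rank-sum p across bins."""
    rows = []
    for name, region in regions.items():
        bins = track.matrix.bin_range(region)
        if len(bins) == 0:
            raise ValueError(f"region {name!r} maps to no bins")
        a = track.pc1[bins]
        b = other.pc1[bins]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        mean_a, mean_b = a.mean(), b.mean()
        ratio = round(abs(mean_b) / abs(mean_a), 2) if mean_a != 0 else np.inf
        if np.array_equal(a, b):
            p = 1.0
        else:
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        rows.append(
            {"region": name, "mean_pc1_self": mean_a, "mean_pc1_other": mean_b,
             "magnitude_ratio": ratio, "p_value": p, "n_bins": len(bins)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TADs
# ---------------------------------------------------------------------------

@dataclass
class TadSet:
    """Insulation-score TAD segmentation of one contact matrix."""

    matrix: ContactMatrix
    insulation: np.ndarray  # normalised log2 insulation, nan at edges
    boundaries: List[int]  # bin indices, strictly increasing
    domains: List[Tuple[int, int]]  # half-open bin spans tiling the segment
    params: Dict[str, float] = field(default_factory=dict)

    def boundary_intervals(self) -> List[GenomicInterval]:
        return [self.matrix.bin_interval(b) for b in self.boundaries]


def insulation_score(m: ContactMatrix, window: int = 10) -> np.ndarray:
    """Per-bin insulation: mean contacts in the window x window square
    crossing the diagonal at each bin, log2-normalised by its mean."""
    n = m.n_bins
    raw = np.full(n, np.nan)
    c = m.counts
    for i in range(window, n - window):
        raw[i] = c[i - window : i, i + 1 : i + 1 + window].mean()
    valid = np.isfinite(raw) & (raw > 0)
    score = np.full(n, np.nan)
    score[valid] = np.log2(raw[valid] / raw[valid].mean())
    return score


def find_tads(
    m: ContactMatrix,
    insulation_window: int = 10,
    delta: float = 0.1,
    significance: float = 0.01,
) -> TadSet:
    """Call TAD boundaries at insulation-score minima.

    Candidate boundaries are local minima of the insulation score with
    prominence >= ``delta``; each candidate must also show significantly
    weaker cross-boundary than within-side contacts (one-sided rank-sum,
    BH-adjusted across candidates at ``significance``).  Domains span the
    segment between consecutive boundaries.
    """
    if m.n_bins < 2 * insulation_window + 1:
        raise ValueError("matrix smaller than insulation window")
    score = insulation_score(m, insulation_window)
    filled = np.where(np.isfinite(score), score, np.nanmax(score) if np.isfinite(score).any() else 0)
    minima, props = signal.find_peaks(-filled, prominence=delta)
    w = insulation_window
    pvals = []
    for i in minima:
        cross = m.counts[i - w : i, i + 1 : i + 1 + w].ravel()
        left = m.counts[i - w : i, i - w : i][np.triu_indices(w, 1)]
        right = m.counts[i + 1 : i + 1 + w, i + 1 : i + 1 + w][np.triu_indices(w, 1)]
        within = np.concatenate([left, right])
        if len(cross) < 3 or len(within) < 3 or np.all(cross == within.mean()):
            pvals.append(1.0)
            continue
        pvals.append(stats.mannwhitneyu(cross, within, alternative="less").pvalue)
    if len(minima):
        keep = multipletests(pvals, alpha=significance, method="fdr_bh")[0]
        boundaries = [int(b) for b, k in zip(minima, keep) if k]
    else:
        boundaries = []
    edges = [0] + boundaries + [m.n_bins]
    domains = [(edges[k], edges[k + 1]) for k in range(len(edges) - 1) if edges[k] < edges[k + 1]]
    return TadSet(
        matrix=m,
        insulation=score,
        boundaries=boundaries,
        domains=domains,
        params={"insulation_window": insulation_window, "delta": delta, "significance": significance},
    )


def compare_boundaries(
    tads_a: TadSet,
    tads_b: TadSet,
    features: Sequence[GenomicInterval] = (),
    slack: int = 2,
) -> pd.DataFrame:
    """Match boundaries between two TAD sets within ``slack`` bins.

    Returns one row per boundary with status ``shared`` (present in both),
    ``lost`` (only in a) or ``gained`` (only in b); gained boundaries are
    annotated with the names of overlapping ``features`` (e.g. DMWs).
    """
    if tads_a.matrix.resolution != tads_b.matrix.resolution:
        raise ValueError("TAD sets at different resolutions")
    a = list(tads_a.boundaries)
    b = list(tads_b.boundaries)
    matched_b: Set[int] = set()
    rows = []
    for ba in a:
        cand = [bb for bb in b if bb not in matched_b and abs(bb - ba) <= slack]
        if cand:
            bb = min(cand, key=lambda x: abs(x - ba))
            matched_b.add(bb)
            rows.append({"bin_a": ba, "bin_b": bb, "status": "shared", "features": ""})
        else:
            rows.append({"bin_a": ba, "bin_b": -1, "status": "lost", "features": ""})
    for bb in b:
        if bb in matched_b:
            continue
        iv = tads_b.matrix.bin_interval(bb)
        names = [
            f.name or f"{f.chrom}:{f.start}-{f.end}"
            for f in features
            if f.overlaps(iv)
        ]
        rows.append({"bin_a": -1, "bin_b": bb, "status": "gained", "features": ",".join(names)})
    return pd.DataFrame(rows, columns=["bin_a", "bin_b", "status", "features"])
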