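"""Synthetic genomes, ChIP/Input count tracks, and Hi-C contact matrices
with planted ground truth.

Every generator is deterministic under a fixed seed and records what it
planted in a :class:`TruthSet`, so downstream callers (domain caller, DMW
caller, motif scanners, compartment/TAD callers) can be scored by recovery
of known truth rather than by comparison to any external dataset.

Count noise is negative binomial (gamma-mixed Poisson), the standard model
for ChIP-seq window counts; dispersion 0 degenerates to Poisson.  Replicates
share the planted truth but draw independent noise from per-replicate
sub-streams of the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .hic import ContactMatrix
from .intervals import GenomicInterval, merge, subtract, total_length
from .io import SequenceRecord
from .windows import ChromSizes, CoverageTrack, WindowGrid, make_windows

__all__ = [
    "TruthSet",
    "SimulationConfig",
    "ContractionSimulation",
    "simulate_genome",
    "simulate_chip_experiment",
    "simulate_contraction_system",
    "simulate_contact_matrix",
    "motif_instance",
]

CHROM = "chr1"


@dataclass
class TruthSet:
    """Planted ground truth for one simulation."""

    centromeres: Dict[str, List[GenomicInterval]] = field(default_factory=dict)
    r1: List[GenomicInterval] = field(default_factory=list)
    r2: List[GenomicInterval] = field(default_factory=list)
    mark_multipliers: Dict[str, Dict[str, float]] = field(default_factory=dict)
    motif_positions: Dict[str, List[GenomicInterval]] = field(default_factory=dict)
    compartment_labels: Optional[np.ndarray] = None
    tad_boundaries: List[int] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r1 or self.r2:
            parent = self.centromeres.get("parent", [])
            if merge(self.r1 + self.r2) != merge(parent):
                raise ValueError("R1 union R2 must equal the parent centromere")
            if total_length(self.r1) + total_length(self.r2) != total_length(parent):
                raise ValueError("R1 and R2 must be disjoint")
        for mults in self.mark_multipliers.values():
            if any(m <= 0 for m in mults.values()):
                raise ValueError("multipliers must be > 0")


@dataclass
class SimulationConfig:
    """Knobs for count-track simulation.

    ``background`` is the expected Input read count per bin; ``enrichment``
    the ChIP/Input fold inside the planted centromere; ``dispersion`` the
    negative-binomial overdispersion (variance = mu + dispersion * mu^2,
    0 = Poisson).  ``genome_size`` models the simulated segment as a slice
    of a larger genome: library sizes include the expected background read
    count off the segment, so a megabase-scale enriched domain does not
    distort the genome-wide normalisation the way it would if the segment
    were the whole genome.
    """

    chrom_length: int = 5_000_000
    bin_width: int = 10_000
    enrichment: float = 10.0
    background: float = 50.0
    dispersion: float = 0.05
    replicates: int = 2
    flank: int = 5_000_000
    genome_size: int = 100_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.chrom_length, self.bin_width, self.replicates) <= 0:
            raise ValueError("sizes and replicate count must be > 0")
        if self.genome_size < self.chrom_length:
            raise ValueError("genome_size must be >= chrom_length")
        if self.enrichment <= 0 or self.background <= 0:
            raise ValueError("rates and folds must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def grid(self) -> WindowGrid:
        return make_windows(ChromSizes({CHROM: self.chrom_length}), self.bin_width)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson mixture; Poisson when dispersion 0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean).astype(float)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam).astype(float)


# ---------------------------------------------------------------------------
# genome + motif planting
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGT", "TGCA")

# fixed aperiodic spacer free of every motif class (no 3+ homopolymer run,
# no G3/C3, no tandem unit, no long purine/pyrimidine alternation)
_SPACER = "CTAGGACTTCAGCAT"


def motif_instance(motif_class: str, rng: np.random.Generator) -> str:
    """One randomly parameterised instance of a non-B motif class."""
    bases = "ACGT"
    if motif_class == "APR":
        n_tracts = int(rng.integers(3, 6))
        base = rng.choice(["A", "T"])
        parts = []
        for t in range(n_tracts):
            tract = base * int(rng.integers(4, 8))
            parts.append(tract)
            if t < n_tracts - 1:
                spacer_len = int(rng.integers(4, 7))
                parts.append("".join(rng.choice(["G", "C"], size=spacer_len)))
        return "".join(parts)
    if motif_class == "GQ":
        loop = lambda: "".join(rng.choice(["T", "A", "C"], size=int(rng.integers(1, 5))))
        return "GGG" + "".join(loop() + "GGG" for _ in range(3))
    if motif_class == "DR":
        unit = "".join(rng.choice(list(bases), size=int(rng.integers(12, 21))))
        return unit * int(rng.integers(2, 4))
    if motif_class == "IR":
        arm = "".join(rng.choice(list(bases), size=int(rng.integers(12, 16))))
        loop_seq = "".join(rng.choice(list(bases), size=int(rng.integers(4, 9))))
        return arm + loop_seq + arm.translate(_COMP)[::-1]
    if motif_class == "MR":
        arm = "".join(rng.choice(list(bases), size=int(rng.integers(12, 16))))
        loop_seq = "".join(rng.choice(list(bases), size=int(rng.integers(4, 9))))
        return arm + loop_seq + arm[::-1]
    if motif_class == "STR":
        unit = "".join(rng.choice(list(bases), size=int(rng.integers(2, 5))))
        reps = int(np.ceil(24 / len(unit)))
        return unit * reps
    if motif_class == "Z":
        return rng.choice(["GC", "CA", "GT"]) * int(rng.integers(7, 11))
    raise ValueError(f"unknown motif class {motif_class!r}")


def simulate_genome(
    length: int,
    gc: float = 0.35,
    plantings: Sequence[Tuple[str, int, int]] = (),
    seed: int = 0,
    chrom: str = CHROM,
) -> Tuple[SequenceRecord, TruthSet]:
    """Random genome with motif instances planted at known positions.

    ``plantings`` lists ``(motif_class, locus, count)``: ``count`` instances
    of the class are written starting at ``locus``, separated by a fixed
    motif-free spacer, overwriting the i.i.d. background (base composition
    with the stated GC, AT and GC each split evenly).  Overlapping planted
    blocks are an error.  The returned truth records every planted span.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0)))
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = rng.choice(list("ACGT"), size=length, p=p)
    truth = TruthSet(seed=seed)
    placed: List[GenomicInterval] = []
    for motif_class, locus, count in plantings:
        pos = locus
        block_start = locus
        for _ in range(count):
            inst = motif_instance(motif_class, rng)
            if pos + len(inst) > length:
                raise ValueError(f"planting at {locus} exceeds genome length")
            seq[pos : pos + len(inst)] = list(inst)
            truth.motif_positions.setdefault(motif_class, []).append(
                GenomicInterval(chrom, pos, pos + len(inst), name=motif_class)
            )
            pos += len(inst)
            seq[pos : pos + len(_SPACER)] = list(_SPACER)
            pos += len(_SPACER)
        block = GenomicInterval(chrom, block_start, pos)
        if any(block.overlaps(other) for other in placed):
            raise ValueError(f"planting blocks overlap at {motif_class} locus {locus}")
        placed.append(block)
    return SequenceRecord(chrom, "".join(seq)), truth


# ---------------------------------------------------------------------------
# ChIP/Input count tracks
# ---------------------------------------------------------------------------

def _region_mask(grid: WindowGrid, regions: Sequence[GenomicInterval]) -> np.ndarray:
    mids = grid.midpoints()
    chroms = np.array([w.chrom for w in grid.windows])
    mask = np.zeros(grid.n_windows, dtype=bool)
    for iv in regions:
        mask |= (chroms == iv.chrom) & (mids >= iv.start) & (mids < iv.end)
    return mask


def _draw_pair(
    grid: WindowGrid,
    chip_mean: np.ndarray,
    input_mean: np.ndarray,
    config: SimulationConfig,
    seed_tuple: Tuple[int, ...],
    sample: str,
    mark: str,
    replicate: int,
) -> Tuple[CoverageTrack, CoverageTrack]:
    rng = np.random.default_rng(np.random.SeedSequence(seed_tuple))
    chip = _nb_draw(rng, chip_mean, config.dispersion)
    inp = _nb_draw(rng, input_mean, config.dispersion)
    # the simulated segment is a slice of a larger genome: the library size is
    # the realized segment total plus the expected background off the segment
    off_segment = config.background * (config.genome_size - config.chrom_length) / config.bin_width
    mk = lambda c: CoverageTrack(
        grid, c, library_size=max(c.sum() + off_segment, 1.0),
        sample=sample, mark=mark, replicate=replicate,
    )
    return mk(chip), mk(inp)


def simulate_chip_experiment(
    truth: TruthSet,
    config: SimulationConfig,
    sample: str = "parent",
    mark: str = "CENH3",
) -> List[Tuple[CoverageTrack, CoverageTrack]]:
    """Paired (ChIP, Input) replicate tracks with enrichment inside the
    sample's planted centromere."""
    grid = config.grid()
    inside = _region_mask(grid, truth.centromeres.get(sample, []))
    input_mean = np.full(grid.n_windows, config.background)
    chip_mean = input_mean * np.where(inside, config.enrichment, 1.0)
    return [
        _draw_pair(grid, chip_mean, input_mean, config, (config.seed, 1, rep), sample, mark, rep)
        for rep in range(config.replicates)
    ]


@dataclass
class ContractionSimulation:
    """Multi-sample track bundle from :func:`simulate_contraction_system`."""

    truth: TruthSet
    grid: WindowGrid
    cenh3: Dict[str, List[Tuple[CoverageTrack, CoverageTrack]]]
    marks: Dict[Tuple[str, str], List[Tuple[CoverageTrack, CoverageTrack]]]


def simulate_contraction_system(
    parent_centromere: GenomicInterval,
    loss_intervals: Sequence[GenomicInterval],
    mark_elevation: Dict[str, Tuple[float, float]],
    decay_scale: float = 1_000_000.0,
    config: Optional[SimulationConfig] = None,
) -> ContractionSimulation:
    """Parent + derived sample system with a contracted centromere.

    The derived sample loses CENH3 enrichment over ``loss_intervals`` (the
    R1 truth); each histone mark in ``mark_elevation`` maps to
    ``(r1_multiplier, r2_multiplier)`` with ``r1 >= r2 >= 1`` — the derived
    sample's mark signal is scaled by those factors inside the centromere and
    by a multiplier decaying exponentially (scale ``decay_scale`` bp, from
    the R1 level at the centromere edge) across the flanking 5 Mb.
    """
    config = config or SimulationConfig()
    loss = merge(loss_intervals)
    for iv in loss:
        if not parent_centromere.contains(iv):
            raise ValueError(f"loss interval {iv} outside parent centromere")
    r2 = subtract([parent_centromere], loss)
    for mark, (m1, m2) in mark_elevation.items():
        if not (m1 >= m2 >= 1.0):
            raise ValueError(f"{mark}: require r1_mult >= r2_mult >= 1, got {m1}, {m2}")
    truth = TruthSet(
        centromeres={"parent": [parent_centromere], "derived": r2},
        r1=loss,
        r2=r2,
        mark_multipliers={m: {"R1": v[0], "R2": v[1]} for m, v in mark_elevation.items()},
        seed=config.seed,
    )

    grid = config.grid()
    mids = grid.midpoints().astype(float)
    background = np.full(grid.n_windows, config.background)
    in_parent = _region_mask(grid, [parent_centromere])
    in_r1 = _region_mask(grid, loss)
    in_r2 = _region_mask(grid, r2)

    cenh3: Dict[str, List[Tuple[CoverageTrack, CoverageTrack]]] = {}
    for si, (sample, region_mask) in enumerate((("parent", in_parent), ("derived", in_r2))):
        chip_mean = background * np.where(region_mask, config.enrichment, 1.0)
        cenh3[sample] = [
            _draw_pair(grid, chip_mean, background, config, (config.seed, 2, si, rep), sample, "CENH3", rep)
            for rep in range(config.replicates)
        ]

    # distance from the centromere edge, 0 inside
    dist = np.where(
        mids < parent_centromere.start,
        parent_centromere.start - mids,
        np.where(mids >= parent_centromere.end, mids - parent_centromere.end + 1, 0.0),
    )
    marks: Dict[Tuple[str, str], List[Tuple[CoverageTrack, CoverageTrack]]] = {}
    for mi, (mark, (m1, m2)) in enumerate(sorted(mark_elevation.items())):
        parent_mean = background.copy()
        mult = np.ones(grid.n_windows)
        mult[in_r1] = m1
        mult[in_r2] = m2
        flank = (~in_parent) & (dist <= config.flank)
        mult[flank] = 1.0 + (m1 - 1.0) * np.exp(-dist[flank] / decay_scale)
        derived_mean = background * mult
        for si, (sample, mean) in enumerate((("parent", parent_mean), ("derived", derived_mean))):
            marks[(sample, mark)] = [
                _draw_pair(grid, mean, background, config, (config.seed, 3, mi, si, rep), sample, mark, rep)
                for rep in range(config.replicates)
            ]
    return ContractionSimulation(truth=truth, grid=grid, cenh3=cenh3, marks=marks)


# ---------------------------------------------------------------------------
# Hi-C contact matrices
# ---------------------------------------------------------------------------

def simulate_contact_matrix(
    n_bins: int,
    decay_exponent: float = 1.0,
    compartment_labels: Optional[Sequence[str]] = None,
    tad_boundaries: Sequence[int] = (),
    depth: float = 2e6,
    seed: int = 0,
    resolution: int = 20_000,
    compartment_affinity: float = 1.5,
    tad_boost: float = 2.0,
) -> Tuple[ContactMatrix, TruthSet]:
    """Symmetric Poisson contact matrix with power-law distance decay,
    optional A/B plaid structure and planted TAD blocks.

    Expected contacts: ``mu(i,j) ~ (|i-j|+1)^-decay * affinity * block``,
    where ``affinity = compartment_affinity`` when bins i and j share a
    compartment label (1 otherwise) and ``block = tad_boost`` when they fall
    inside the same TAD (between consecutive planted boundaries).  The matrix
    is scaled so the expected total is ``depth`` and the upper triangle is
    drawn Poisson then mirrored.
    """
    if n_bins < 20:
        raise ValueError("n_bins must be >= 20")
    for b in tad_boundaries:
        if not 0 < b < n_bins:
            raise ValueError(f"TAD boundary {b} not strictly inside (0, {n_bins})")
    idx = np.arange(n_bins)
    mu = (np.abs(idx[:, None] - idx[None, :]) + 1.0) ** (-decay_exponent)
    labels = None
    if compartment_labels is not None:
        labels = np.asarray(list(compartment_labels))
        if labels.shape != (n_bins,) or not set(labels) <= {"A", "B"}:
            raise ValueError("compartment_labels must be n_bins letters from {A, B}")
        same = labels[:, None] == labels[None, :]
        mu *= np.where(same, compartment_affinity, 1.0)
    if len(tad_boundaries):
        edges = np.concatenate([[0], np.sort(tad_boundaries), [n_bins]])
        block_id = np.searchsorted(edges, idx, side="right")
        mu *= np.where(block_id[:, None] == block_id[None, :], tad_boost, 1.0)
    mu *= depth / mu.sum()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x41C)))
    upper = rng.poisson(np.triu(mu)).astype(float)
    counts = np.triu(upper) + np.triu(upper, 1).T
    truth = TruthSet(
        compartment_labels=labels,
        tad_boundaries=sorted(int(b) for b in tad_boundaries),
        seed=seed,
    )
    return ContactMatrix(counts=counts, resolution=resolution, chrom=CHROM), truth
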