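# Methods

This note documents the models, parameter choices and numerical decisions
behind `cendyn`, in the spirit of a package reference: what each stage
assumes, which knobs matter, and what the synthetic-data tests do and do
not establish about real data.

## Coordinates and windowing

All coordinates are 0-based half-open (the BED convention).  Published
megabase coordinates rounded to 0.01 Mb are converted on input; because of
that rounding, exact base-pair boundaries of published centromeres are not
recoverable, and comparisons against printed coordinates use a ±10 kb
tolerance.  Window grids tile each chromosome from position 0 with a fixed
width (5 kb for differential-modification windows, 200 kb for motif
densities, 1 Mb for pericentromere boxes); the truncated trailing window is
kept, matching the behaviour of the standard windowing tools.  Reads and
intervals are assigned to the window containing their midpoint, which
avoids double counting across boundaries.

## Count model and the synthetic-data generator

Window counts are modelled as negative binomial: variance = μ + φμ², with
dispersion φ = 0 giving Poisson.  NB is the standard model for ChIP-seq
window counts across biological replicates and is what the usual
differential-count machinery assumes.  Generator defaults:

| parameter | default | meaning |
|---|---|---|
| `chrom_length` | 5 Mb | simulated chromosome segment |
| `bin_width` | 10 kb | count bins |
| `enrichment` | 10 | ChIP/Input fold inside the planted centromere |
| `background` | 50 reads/bin | Input mean per bin |
| `dispersion` | 0.05 | NB overdispersion (biological replicates) |
| `replicates` | 2 | biological replicates per condition |
| `genome_size` | 100 Mb | genome the segment is a slice of |
| `flank` | 5 Mb | pericentromere extent per side |

`genome_size` matters: a library size is a genome-wide read total, so the
track's library is the realized segment total plus the expected background
off the segment.  Without this, a megabase-scale enriched domain on a small
simulated segment inflates its own library enough to halve every measured
fold change — an artifact of simulating a segment as if it were the whole
genome, not a feature of the assay.

Contraction systems plant a parental centromere, remove the enrichment
over the lost (R1) intervals in the derived sample, scale each histone
mark by per-region multipliers (R1 ≥ R2 ≥ 1) inside the centromere, and
let the elevation decay exponentially with distance from the centromere
edge across the flank.  The exponential is the simplest monotone decay
with a single recoverable scale parameter; recovery tests fit it back
within 25%.  Replicates share the planted truth and draw independent noise
from per-replicate substreams of the master seed, so every output is
byte-identical under a fixed seed.

Contact matrices use μ(i,j) ∝ (|i−j|+1)^(−α) with a same-compartment
affinity factor (default 1.5) on plaid labels and a within-TAD boost
(default 2.0), Poisson-sampled on the upper triangle and mirrored; the
expected total is the sequencing depth (default 2×10⁶ over ~100 bins).

What the generator does **not** emulate: read-level artefacts (mappability,
GC bias, duplicates), sequence-dependent ChIP efficiency, copy-number
variation, Hi-C ligation artefacts, or trans contacts.  Passing recovery
tests therefore demonstrates the correctness of the estimators under the
stated count model, not robustness to every real-data pathology.

## Domain calling

Binned fold change uses a pseudocount of 1 read in both numerator and
denominator, keeping the ratio finite in empty windows.  Domains are
maximal runs of bins with FC above threshold (default 4), merged across
gaps ≤ 100 kb and dropped below 50 kb — centromeres are megabase-scale and
contiguous at this resolution, and both values are configurable.  For
domain calling the pipeline pools replicates first; pooling halves the
effective noise and makes boundary recovery exact to one bin in the
default conditions.  The contraction direction label names an arm when at
least 80% of lost bases fall on that side ("almost unidirectional" made
precise); orientation is supplied per chromosome as a
"left-is-short-arm" flag.

## Differential modification windows

Region fold-change tests pool replicates and use Fisher's exact test on
[[count, library − count], …]; the p-value is verified against an
exhaustive hypergeometric enumeration.  The window-level DMW caller is an
in-repo exact-style NB test: replicate sums per condition are NB with
dispersion φ/r; conditioning on the pooled window total, the two-sided p
sums the probabilities of all splits no likelier than the observed one.
The common dispersion comes from a pooled method-of-moments estimator,
Σ(var − mean)/Σ(mean² − var/r), whose denominator correction removes the
small-replicate bias (a per-window median estimator is badly biased with
two replicates).  BH adjustment runs across all windows of one contrast on
one chromosome; calls additionally require |FC| > 1.5 on library-normalised
means with pseudocount 0.5.  Null p-values are verified uniform; note that
BH controls the *expected* false-discovery proportion, so finite-seed
empirical FDP is checked for consistency with the nominal level via a
binomial bound rather than asserted to sit below it point-wise.

With two replicates and φ = 0.05 the discriminability of a 3-fold change
saturates near z ≈ ln 3 / √(2φ/r) ≈ 4.9 regardless of depth — a dispersion
floor.  Measured sensitivity at the default conditions is ≈ 0.93 with
empirical FDP ≈ 0.04–0.06.

## Non-B DNA

Scanner rules are stated explicitly in `cendyn.nonb` (tract/spacer bounds
for A-phased repeats, G-run/loop bounds for G-quadruplex, arm/loop bounds
for inverted and mirror repeats, unit/span bounds for tandem repeats,
dinucleotide-step alphabet for Z-DNA).  Two refinements keep the classes
disjoint from degenerate cases: direct-repeat units and mirror-repeat arms
must contain at least two distinct bases (a homopolymer is an STR and is
trivially its own mirror image).  Every scanner is required to equal an
independent brute-force rule-checker exactly on random sequences; hits are
maximal and non-redundant (no hit contained in another of its class).

The windowed stability score is the unified nearest-neighbour duplex free
energy (ΔG°37 stack sum plus initiation, kcal/mol) over 300-nt windows
stepped by 150 nt.  This is a duplex-thermodynamics score, not a
single-strand folding minimum-free-energy computation; an `external`
engine hook accepts a table of scores from any folding program, and all
region comparisons (R1 vs R2 vs non-centromeric, rank-sum tests) are
engine-consistent.

The permutation enrichment test draws |cen| windows without replacement
from the non-centromeric pool (n = 1000 by default) and reports
p = (1 + #{null ≥ observed}) / (n + 1); ties count against enrichment, so
a flat genome yields p = 1.

## Hi-C

Knight–Ruiz balancing implements the inexact-Newton inner-CG algorithm;
bins with zero marginal are masked first, the result preserves the input
total, and the unmasked row-sum coefficient of variation must fall below
the tolerance (default 1e-6; verified against an iterative-proportional-
fitting oracle).  Difference maps are computed as log2(a+ε) − log2(b+ε) so
antisymmetry under operand swap is bitwise exact.

Compartments: observed/expected by per-diagonal means, Pearson correlation
matrix, first principal component; sign is anchored by a configurable
orientation track (gene density by convention, A = gene-rich), since the
eigenvector sign is arbitrary.  One caveat documented by the tests: on a
finite power-law segment, KR balancing itself induces a smooth positional
component in the O/E correlation, so a featureless simulation does not
have a near-zero PC1 share on the KR matrix (it does on the depth-
normalised matrix); planted compartment labels are nevertheless recovered
at ≥ 95% because plaid structure dominates the spectrum when present.

TADs: per-bin insulation is the mean of the w×w square crossing the
diagonal (default w = 10 bins), log2-normalised by its chromosome mean.
Boundaries are local minima with prominence ≥ δ (default 0.1) that also
show significantly weaker cross-boundary than within-side contacts
(one-sided rank-sum, BH across candidates at FDR 0.01).  Domains tile the
segment between boundaries.  Boundary sets are matched greedily within a
slack (default 2 bins); unmatched boundaries are lost/gained, and gained
boundaries are annotated with overlapping features such as DMWs.

## Pipeline

Stages run in dependency order (`diffmod` needs `centromeres`); a failing
stage blocks only its dependents.  Track bedGraphs must tile the
configured grid exactly; per-track genome-wide library sizes can (and for
segment data should) be supplied in the config, since a segment sum
understates the library.  The manifest records package version, seed,
parameters, input SHA-256 hashes, and per-stage outputs; stage wall-times
are recorded for convenience and are the only non-deterministic manifest
field — all analysis outputs are byte-identical across reruns with the
same seed.

## Problem sizes used by the test suite

The suite and acceptance script run at deliberately modest sizes chosen to
exercise every code path with tight statistical margins: 5-Mb segments at
10-kb bins for domain recovery (50 seeds), 1 000 windows × 20 seeds for DMW
recovery, 100-bin matrices for compartments and 90-bin matrices for TADs
(10–20 seeds), 5-kb sequences × 50 per class for scanner-oracle
equivalence, and 100–200 repetitions for calibration checks.

## Known limitations

- The DMW test assumes a common dispersion; strongly mark-specific or
  mean-dependent dispersion would call for a trended estimator.
- Compartment calling returns the first principal component only; in
  degenerate segments where a positional artefact dominates, inspecting
  the second component (and the orientation anchor) is advisable.
- The insulation TAD caller is single-scale; nested domain hierarchies are
  out of scope.
- Motif scanning is exact-match (no mismatch tolerance in direct-repeat
  units or arms); scanner parameters are config-exposed for looser runs.
- The pipeline operates per chromosome segment; trans-chromosomal Hi-C
  structure is not modelled.
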