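import numpy as np
import pytest

from cendyn.intervals import ChromSizes, GenomicInterval


@pytest.fixture
def toy_sizes():
    return ChromSizes({"chr1": 10_000, "chr2": 12_000})


def random_intervals(rng: np.random.Generator, chrom: str, n: int, span: int):
    """Random small interval set on [0, span) for oracle comparisons."""
    out = []
    for _ in range(n):
        s = int(rng.integers(0, span - 1))
        e = int(rng.integers(s + 1, min(s + span // 5 + 2, span) + 1))
        out.append(GenomicInterval(chrom, s, e))
    return out


def coverage_mask(ivs, span: int) -> np.ndarray:
    """Per-base boolean membership array — the interval-algebra oracle."""
    mask = np.zeros(span, dtype=bool)
    for iv in ivs:
        mask[iv.start : iv.end] = True
    return mask
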