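"""Independent brute-force oracles for the non-B motif class rules.

Each oracle enumerates candidate spans directly from the stated sequence
rule (regex run-finding, exhaustive pair tables, per-start extension) and
keeps maximal spans by containment — sharing no code with the package's
scanners.
"""

import re

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def _maximal(spans):
    spans = sorted(set(spans))
    out = []
    for s, e in spans:
        contained = any(
            (s2 <= s and e <= e2) and (s2, e2) != (s, e) for s2, e2 in spans
        )
        if not contained:
            out.append((s, e))
    return out


def _chains(runs, min_runs, gap_lo, gap_hi):
    spans = []
    for i in range(len(runs)):
        for j in range(i + min_runs - 1, len(runs)):
            gaps = [runs[k + 1][0] - runs[k][1] for k in range(i, j)]
            if all(gap_lo <= g <= gap_hi for g in gaps):
                spans.append((runs[i][0], runs[j][1]))
    return _maximal(spans)


def apr_oracle(seq):
    tracts = sorted(
        (m.start(), m.end())
        for m in re.finditer(r"A+|T+", seq)
        if 3 <= m.end() - m.start() <= 9
    )
    return _chains(tracts, 3, 4, 9)


def gq_oracle(seq):
    out = []
    for base in ("G", "C"):
        runs = sorted(
            (m.start(), m.end())
            for m in re.finditer(base + "{3,}", seq)
        )
        out.extend(_chains(runs, 4, 1, 7))
    return sorted(out)


def z_oracle(seq):
    allowed = {"GC", "CG", "CA", "AC", "GT", "TG"}
    spans = []
    i = 0
    n = len(seq)
    while i < n - 1:
        j = i
        while j < n - 1 and seq[j : j + 2] in allowed:
            j += 1
        if j > i and (j + 1 - i) >= 12:
            spans.append((i, j + 1))
        i = max(j, i + 1)
    return _maximal(spans)


def tandem_oracle(seq, unit_lo, unit_hi, min_span, mixed_unit=False):
    """min_span: callable unit -> minimum total span; mixed_unit requires
    the repeat unit to contain >= 2 distinct bases."""
    n = len(seq)
    spans = []
    for u in range(unit_lo, unit_hi + 1):
        i = 0
        while i + 2 * u <= n:
            if seq[i] != "N" and i + u < n and seq[i] == seq[i + u]:
                j = i
                while j + u < n and seq[j] == seq[j + u] and seq[j] != "N":
                    j += 1
                span = (i, j + u)
                if span[1] - span[0] >= max(min_span(u), 2 * u) and (
                    not mixed_unit or len(set(seq[i : i + u])) >= 2
                ):
                    spans.append(span)
                i = j + 1
            else:
                i += 1
    return _maximal(spans)


def palindrome_oracle(seq, mirror, min_arm=10, max_loop=100):
    """Exhaustive innermost-pair table for inverted/mirror repeats."""
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    partner = arr if mirror else np.frombuffer(
        seq.translate(_COMP).encode(), dtype=np.uint8
    )
    valid = arr != ord("N")
    spans = []
    for gap in range(0, max_loop + 1):
        # match(x, y) <=> arr[x] == partner[y]; here y = x + gap + 1
        m = (arr[: n - gap - 1] == partner[gap + 1 :]) & valid[: n - gap - 1] & valid[gap + 1 :]
        for u in np.nonzero(m)[0]:
            v = u + gap + 1
            if gap >= 2 and valid[u + 1] and valid[v - 1] and arr[u + 1] == partner[v - 1]:
                continue  # extendable inward: not the innermost pair
            a = 1
            while (
                u - a >= 0 and v + a < n
                and valid[u - a] and valid[v + a]
                and arr[u - a] == partner[v + a]
            ):
                a += 1
            if a >= min_arm and not (
                mirror and len(set(seq[u - a + 1 : u + 1])) < 2
            ):
                spans.append((u - a + 1, v + a))
    return _maximal(spans)
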