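"""Shared fixtures and independent reference implementations.

The reference scanner below is a deliberately naive position-by-position
implementation (no ``str.find``, no shared code with the package) used as
the oracle for equivalence testing, and the enumerator computes dyad
probabilities by weighing every sequence of a given length explicitly.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from beldyad.scan import classify_orientation

# ---------------------------------------------------------------------------
# naive reference scanner

def ref_find_cores(sequence: str) -> list[tuple[int, int, str]]:
    """All maximal core hits as (start, length, strand), by direct comparison."""
    s = sequence.upper()
    n = len(s)
    hits = []
    for i in range(n):
        if s[i : i + 5] == "TTGAC":
            hits.append((i, 5, "+"))
        elif s[i : i + 4] == "TGAC" and not (i > 0 and s[i - 1] == "T"):
            hits.append((i, 4, "+"))
        if s[i : i + 5] == "GTCAA":
            hits.append((i, 5, "-"))
        elif s[i : i + 4] == "GTCA" and not (i + 4 < n and s[i + 4] == "A"):
            hits.append((i, 4, "-"))
    return sorted(hits)


def ref_dyads(sequence: str, max_linker: int) -> set[tuple]:
    """All dyads as structural tuples, by exhaustive O(n^2) pairing."""
    cores = ref_find_cores(sequence)
    out = set()
    for a in cores:
        for b in cores:
            if a == b:
                continue
            linker = b[0] - (a[0] + a[1])
            if 0 <= linker <= max_linker:
                out.add((a, b, linker, classify_orientation(a[2], b[2])))
    return out


def dyad_key(d) -> tuple:
    """Structural tuple of a package DyadElement, comparable with ref_dyads."""
    return (
        (d.left.start, d.left.length, d.left.strand),
        (d.right.start, d.right.length, d.right.strand),
        d.linker_length,
        d.orientation,
    )


# ---------------------------------------------------------------------------
# exhaustive enumerator for the background probability

_PAT_PLUS = np.array([3, 2, 0, 1], dtype=np.uint8)   # TGAC with A,C,G,T = 0..3
_PAT_MINUS = np.array([2, 3, 1, 0], dtype=np.uint8)  # GTCA


def _dyad_exists(digits: np.ndarray, max_linker: int) -> np.ndarray:
    """Vectorised per-row dyad existence from the maximal-hit definition."""
    m, n = digits.shape
    cores = []  # (match_mask, start_max, end_excl) per 4-mer position/strand
    for p in range(n - 3):
        win = digits[:, p : p + 4]
        mp = (win == _PAT_PLUS).all(axis=1)
        start = np.full(m, p)
        if p > 0:
            start = start - (digits[:, p - 1] == 3)  # preceding T -> TTGAC
        cores.append((mp, start, np.full(m, p + 4)))
        mm = (win == _PAT_MINUS).all(axis=1)
        end = np.full(m, p + 4)
        if p + 4 < n:
            end = end + (digits[:, p + 4] == 0)  # following A -> GTCAA
        cores.append((mm, np.full(m, p), end))
    hit = np.zeros(m, dtype=bool)
    for i, (ma, _, ea) in enumerate(cores):
        for mb, sb, _ in cores[i + 1 :]:
            gap = sb - ea
            hit |= ma & mb & (gap >= 0) & (gap <= max_linker)
    return hit


def enumerated_dyad_probability(n: int, max_linker: int, freqs=(0.25,) * 4) -> float:
    """P(>=1 dyad) by explicit enumeration of all 4**n sequences."""
    freqs = np.asarray(freqs, dtype=float)
    total = 0.0
    big_n = 4**n
    chunk = 1 << 20
    for lo in range(0, big_n, chunk):
        ids = np.arange(lo, min(lo + chunk, big_n), dtype=np.int64)
        digits = np.empty((len(ids), n), dtype=np.uint8)
        x = ids
        for k in range(n - 1, -1, -1):
            digits[:, k] = x & 3
            x = x >> 2
        hit = _dyad_exists(digits, max_linker)
        if hit.any():
            total += np.prod(freqs[digits[hit]], axis=1).sum()
    return float(total)


def all_sequences(length: int):
    for tup in itertools.product("ACGT", repeat=length):
        yield "".join(tup)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230717)


@pytest.fixture()
def random_dna(rng):
    letters = np.array(list("ACGT"))

    def make(length: int) -> str:
        return "".join(rng.choice(letters, size=length))

    return make
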