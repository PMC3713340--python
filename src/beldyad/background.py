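"""Background occurrence statistics for tandem TGAC-core dyads.

Answers "how surprising is one dyad in a 2-kb promoter window?" under an
i.i.d. base-composition null.  Two routes:

* :func:`dyad_probability` — the exact probability that a random window
  contains at least one dyad, by dynamic programming over an Aho–Corasick
  automaton for the core patterns combined with a capped counter of bases
  elapsed since the most recent core end;
* :func:`simulate_dyad_rate` — seeded Monte Carlo through the actual
  scanner, the independent check on the DP.

The DP models *maximal* hits exactly as the scanner does.  This matters: a
right-hand core extended to ``TTGAC`` starts one base earlier than its inner
``TGAC``, shortening the linker by one, so a 4-mer-only model would misclassify
sequences whose gap sits exactly at the linker cap.  The plus-strand
extension is handled by tracking ``TTGAC`` as its own pattern; the
minus-strand extension (a trailing ``A`` turning ``GTCA`` into ``GTCAA``,
which moves that core's *end* one base later) is handled by deferring the
end-position decision one character.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scan import DEFAULT_MAX_LINKER, find_cores, pair_cores

__all__ = ["BackgroundSpec", "expected_core_sites", "dyad_probability", "simulate_dyad_rate"]

_ALPHABET = "ACGT"


@dataclass(frozen=True)
class BackgroundSpec:
    """i.i.d. background model: base frequencies (A, C, G, T), window, linker cap."""

    base_frequencies: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    window_length: int = 2000
    max_linker: int = DEFAULT_MAX_LINKER

    def __post_init__(self):
        f = np.asarray(self.base_frequencies, dtype=float)
        if f.shape != (4,) or (f < 0).any():
            raise ValueError("base_frequencies must be four non-negative reals")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("base_frequencies must sum to 1 within 1e-9")
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")
        if self.max_linker < 0:
            raise ValueError("max_linker must be >= 0")


def expected_core_sites(spec: BackgroundSpec) -> float:
    """Expected number of 4-mer core match positions, both strands.

    Linearity of expectation over the ``window_length - 3`` start positions;
    both ``TGAC`` and its reverse complement ``GTCA`` use each base exactly
    once, so each pattern has probability ``fA*fC*fG*fT`` per position.
    Maximality (the 5-mer extension) is deliberately ignored here: extension
    merges a 4-mer into a 5-mer hit but does not change the number of 4-mer
    match positions being counted.
    """
    n = spec.window_length
    if n < 4:
        return 0.0
    fa, fc, fg, ft = spec.base_frequencies
    return 2.0 * (n - 3) * fa * fc * fg * ft


def _build_automaton(patterns: tuple[str, ...]) -> tuple[np.ndarray, list[set[str]]]:
    """Aho–Corasick goto table and per-state matched-pattern sets."""
    goto: list[dict[str, int]] = [{}]
    out: list[set[str]] = [set()]
    for pat in patterns:
        s = 0
        for ch in pat:
            if ch not in goto[s]:
                goto.append({})
                out.append(set())
                goto[s][ch] = len(goto) - 1
            s = goto[s][ch]
        out[s].add(pat)
    # BFS fail links, then flatten into a dense transition table.
    fail = [0] * len(goto)
    queue = list(goto[0].values())
    for s in queue:
        fail[s] = 0
    while queue:
        s = queue.pop(0)
        for ch, t in goto[s].items():
            queue.append(t)
            f = fail[s]
            while f and ch not in goto[f]:
                f = fail[f]
            fail[t] = goto[f].get(ch, 0) if goto[f].get(ch, 0) != t else 0
            out[t] |= out[fail[t]]
    table = np.zeros((len(goto), 4), dtype=np.int64)
    for s in range(len(goto)):
        for b, ch in enumerate(_ALPHABET):
            t = s
            while t and ch not in goto[t]:
                t = fail[t]
            table[s, b] = goto[t].get(ch, 0)
    return table, out


# Counter codes for "bases since the most recent core's exclusive end":
#   NONE    no core seen yet
#   PENDING a GTCA just completed; whether its end extends by one (GTCAA)
#           depends on the next character
#   0..cap  literal count, saturating at cap (any completion from there on
#           has linker > max_linker)
def dyad_probability(spec: BackgroundSpec) -> float:
    """Exact P(window contains >= 1 dyad) under the i.i.d. background.

    Dynamic programming over (automaton state, counter) with an absorbing
    "dyad found" state; deterministic, O(window * states * 4).
    """
    n, L = spec.window_length, spec.max_linker
    if n < 8:
        return 0.0  # the shortest dyad is two 4-mer cores with linker 0
    table, out = _build_automaton(("TTGAC", "TGAC", "GTCA"))
    n_ac = table.shape[0]
    NONE, PENDING = -2, -1
    cap = L + 6  # counts > L+5 can never yield linker <= L
    codes = [NONE, PENDING] + list(range(cap + 1))
    idx = {c: i for i, c in enumerate(codes)}
    n_codes = len(codes)

    def state_id(ac: int, c: int) -> int:
        return ac * n_codes + idx[c]

    n_states = n_ac * n_codes
    # Precompute transitions: (state, base) -> target state or HIT (-1).
    trans = np.empty((n_states, 4), dtype=np.int64)
    for ac in range(n_ac):
        for c in codes:
            src = state_id(ac, c)
            for b, ch in enumerate(_ALPHABET):
                ac2 = table[ac, b]
                if c == NONE:
                    c2 = NONE
                elif c == PENDING:
                    c2 = 0 if ch == "A" else 1
                else:
                    c2 = min(c + 1, cap)
                matched = out[ac2]
                if matched:
                    if "TTGAC" in matched:
                        gap = None if c2 in (NONE,) else c2 - 5
                        new_c: int = 0
                    elif "TGAC" in matched:
                        gap = None if c2 in (NONE,) else c2 - 4
                        new_c = 0
                    else:  # GTCA
                        gap = None if c2 in (NONE,) else c2 - 4
                        new_c = PENDING
                    if gap is not None and 0 <= gap <= L:
                        trans[src, b] = -1
                        continue
                    c2 = new_c
                trans[src, b] = state_id(ac2, c2)
    freqs = np.asarray(spec.base_frequencies, dtype=float)
    prob = np.zeros(n_states)
    prob[state_id(0, NONE)] = 1.0
    p_hit = 0.0
    for _ in range(n):
        nxt = np.zeros(n_states)
        for b in range(4):
            contrib = prob * freqs[b]
            targets = trans[:, b]
            live = targets >= 0
            np.add.at(nxt, targets[live], contrib[live])
            p_hit += contrib[~live].sum()
        prob = nxt
    return float(p_hit)


def simulate_dyad_rate(spec: BackgroundSpec, n_sims: int, seed: int = 0) -> float:
    """Fraction of seeded random windows in which the scanner finds >= 1 dyad."""
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)
    freqs = np.asarray(spec.base_frequencies, dtype=float)
    hits = 0
    chunk = max(1, min(n_sims, 2_000_000 // max(spec.window_length, 1)))
    done = 0
    while done < n_sims:
        m = min(chunk, n_sims - done)
        mat = letters[rng.choice(4, size=(m, spec.window_length), p=freqs)]
        for row in mat:
            seq = row.tobytes().decode("ascii")
            if "TGAC" in seq or "GTCA" in seq:
                cores = find_cores(seq)
                if len(cores) >= 2 and pair_cores(cores, spec.max_linker):
                    hits += 1
        done += m
    return hits / n_sims
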