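"""Strand-aware scanning for tandem TGAC-core (dyad) cis-elements.

The binding site of BEL1-like/KNOX homeodomain heterodimers (e.g. the potato
StBEL5/POTH1 complex) is a *tandem* arrangement of two TGAC cores separated by
a short linker.  On the plus strand a core reads ``TGAC`` (extended form
``TTGAC``); a core on the opposite strand appears in the scanned window as its
reverse complement ``GTCA`` (extended ``GTCAA``).  This module finds all
maximal core occurrences on both strands, pairs them into dyad elements under
a linker-length constraint, classifies the relative 5'->3' orientation of the
two cores (HtH, HtT, TtH, TtT) and reports the element's distance upstream of
the window anchor.

Conventions
-----------
* Matching is case-insensitive; IUPAC ambiguity codes (``N`` etc.) never match.
* Hits are *maximal*: a 4-mer ``TGAC`` is reported as the 5-mer ``TTGAC`` when
  the preceding base is ``T``; a 4-mer ``GTCA`` is reported as ``GTCAA`` when
  the following base is ``A``.  No longer extensions are considered.
* ``linker_length`` is the number of bases strictly between the two maximal
  cores; a zero-linker dyad (e.g. ``TGACTTGAC``) is an ordinary dyad.
* ``distance_upstream`` counts window positions from the right end (the base
  immediately 5' of the anchor is position 1) to the dyad's 5'-most base.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

__all__ = [
    "CoreHit",
    "DyadElement",
    "find_cores",
    "classify_orientation",
    "pair_cores",
    "scan_sequence",
    "scan_region",
    "DEFAULT_MAX_LINKER",
]

#: Largest linker length reported among the curated potato target elements.
DEFAULT_MAX_LINKER = 24

_ORIENTATION = {
    ("+", "+"): "TtH",
    ("+", "-"): "TtT",
    ("-", "+"): "HtH",
    ("-", "-"): "HtT",
}


@dataclass(frozen=True, order=True)
class CoreHit:
    """One maximal TGAC-core occurrence in a window.

    ``strand`` is ``"+"`` when the window itself reads TGAC/TTGAC at ``start``
    and ``"-"`` when it reads GTCA/GTCAA (core on the opposite strand).
    """

    start: int
    length: int
    strand: str
    text: str

    @property
    def end(self) -> int:
        """Exclusive end offset of the hit."""
        return self.start + self.length


@dataclass(frozen=True)
class DyadElement:
    """An ordered pair of cores forming one tandem element."""

    left: CoreHit
    right: CoreHit
    linker_length: int
    linker_text: str
    orientation: str
    distance_upstream: int | None = None
    gene_id: str | None = None

    @property
    def start(self) -> int:
        return self.left.start

    @property
    def end(self) -> int:
        return self.right.end

    def element_text(self, sequence: str) -> str:
        """The dyad substring of ``sequence`` (cores plus linker)."""
        return sequence[self.left.start : self.right.end]


def find_cores(sequence: str) -> list[CoreHit]:
    """Find all maximal TGAC-core occurrences on both strands.

    Returns hits sorted by start offset.  Maximal hits never overlap (no
    suffix of any core pattern is a prefix of another), a property the rest
    of the pipeline relies on.
    """
    seq = sequence.upper()
    hits: list[CoreHit] = []
    # Plus strand: TGAC, maximal extension with a preceding T -> TTGAC.
    pos = seq.find("TGAC")
    while pos != -1:
        if pos > 0 and seq[pos - 1] == "T":
            hits.append(CoreHit(pos - 1, 5, "+", sequence[pos - 1 : pos + 4]))
        else:
            hits.append(CoreHit(pos, 4, "+", sequence[pos : pos + 4]))
        pos = seq.find("TGAC", pos + 1)
    # Minus strand: GTCA, maximal extension with a following A -> GTCAA.
    pos = seq.find("GTCA")
    while pos != -1:
        if pos + 4 < len(seq) and seq[pos + 4] == "A":
            hits.append(CoreHit(pos, 5, "-", sequence[pos : pos + 5]))
        else:
            hits.append(CoreHit(pos, 4, "-", sequence[pos : pos + 4]))
        pos = seq.find("GTCA", pos + 1)
    hits.sort(key=lambda h: h.start)
    return hits


def classify_orientation(left_strand: str, right_strand: str) -> str:
    """Orientation class of a core pair read left to right.

    A plus-strand core is an arrow pointing right (tail at its left end, head
    at its right end); a minus-strand core points left.  The label reads the
    outermost ends of the two arrows: (+,+) -> TtH, (+,-) -> TtT,
    (-,+) -> HtH, (-,-) -> HtT.
    """
    try:
        return _ORIENTATION[(left_strand, right_strand)]
    except KeyError:
        raise ValueError(f"strands must be '+' or '-', got {left_strand!r}, {right_strand!r}")


def pair_cores(
    cores: Sequence[CoreHit],
    max_linker: int = DEFAULT_MAX_LINKER,
    *,
    sequence: str | None = None,
    adjacent_only: bool = False,
) -> list[DyadElement]:
    """Pair cores into dyad elements under a linker constraint.

    All ordered pairs of distinct cores with ``0 <= linker <= max_linker`` are
    reported (a window with three clustered cores genuinely contains several
    dyads); ``adjacent_only=True`` restricts pairing to consecutive cores.
    ``sequence`` supplies the linker text; without it linker text is empty.
    """
    if max_linker < 0:
        raise ValueError("max_linker must be >= 0")
    dyads: list[DyadElement] = []
    for i, left in enumerate(cores):
        js = [i + 1] if adjacent_only else range(i + 1, len(cores))
        for j in js:
            if j >= len(cores):
                continue
            right = cores[j]
            linker = right.start - left.end
            if linker < 0:
                continue  # defensive: maximal hits never overlap
            if linker > max_linker:
                if adjacent_only:
                    break
                continue
            text = sequence[left.end : right.start] if sequence is not None else ""
            dyads.append(
                DyadElement(
                    left=left,
                    right=right,
                    linker_length=linker,
                    linker_text=text,
                    orientation=classify_orientation(left.strand, right.strand),
                )
            )
    return dyads


def scan_sequence(
    sequence: str,
    max_linker: int = DEFAULT_MAX_LINKER,
    *,
    gene_id: str | None = None,
    adjacent_only: bool = False,
    distance_to: str = "5p",
) -> list[DyadElement]:
    """Scan a bare window sequence for dyad elements.

    ``distance_to`` selects the distance convention: ``"5p"`` (default)
    measures to the dyad's 5'-most base, ``"3p"`` to its 3'-most base; both
    count 1-based from the right (anchor-proximal) end of the window.
    """
    if distance_to not in ("5p", "3p"):
        raise ValueError("distance_to must be '5p' or '3p'")
    n = len(sequence)
    cores = find_cores(sequence)
    dyads = pair_cores(cores, max_linker, sequence=sequence, adjacent_only=adjacent_only)
    out = []
    for d in dyads:
        dist = n - d.start if distance_to == "5p" else n - d.end + 1
        out.append(replace(d, distance_upstream=dist, gene_id=gene_id))
    return out


def scan_region(
    region,
    max_linker: int = DEFAULT_MAX_LINKER,
    max_distance: int | None = None,
    *,
    adjacent_only: bool = False,
    distance_to: str = "5p",
) -> list[DyadElement]:
    """Scan an :class:`~beldyad.upstream.UpstreamRegion` for dyad elements.

    Dyads whose ``distance_upstream`` exceeds ``max_distance`` are dropped
    when a maximum is given.
    """
    dyads = scan_sequence(
        region.sequence,
        max_linker,
        gene_id=region.gene_id,
        adjacent_only=adjacent_only,
        distance_to=distance_to,
    )
    if max_distance is not None:
        dyads = [d for d in dyads if d.distance_upstream <= max_distance]
    return dyads


def scan_windows(
    windows: Iterable[tuple[str, str]],
    max_linker: int = DEFAULT_MAX_LINKER,
    max_distance: int | None = None,
    **kwargs,
) -> list[DyadElement]:
    """Scan an iterable of ``(gene_id, sequence)`` windows."""
    out: list[DyadElement] = []
    for gene_id, seq in windows:
        dyads = scan_sequence(seq, max_linker, gene_id=gene_id, **kwargs)
        if max_distance is not None:
            dyads = [d for d in dyads if d.distance_upstream <= max_distance]
        out.extend(dyads)
    return out
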