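"""Synthetic inputs for exercising the dyad pipeline end to end.

Three generators:

* core-free promoter background — i.i.d. bases at a chosen GC fraction with
  rejection of every ``TGAC``/``GTCA`` 4-mer, which forbids all cores on both
  strands (a minus-strand core would appear on the plus string as one of the
  same two 4-mers);
* promoter sets with deliberately embedded tandem elements plus an exact
  truth table, optionally materialised as a genome FASTA + GFF3 pair so the
  upstream-extraction stage can be exercised;
* replicate qPCR Ct tables with known true fold changes, the inverse of the
  comparative-threshold-cycle (Livak) quantification model.

Everything is seeded and byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .scan import find_cores, scan_sequence, DEFAULT_MAX_LINKER

__all__ = [
    "EmbedPlan",
    "QpcrSimSpec",
    "generate_corefree_background",
    "build_promoter_set",
    "write_windows_fasta",
    "write_promoter_genome",
    "simulate_ct_table",
]

_BASES = np.frombuffer(b"acgt", dtype=np.uint8)
_FORBIDDEN = ("TGAC", "GTCA")


@dataclass(frozen=True)
class EmbedPlan:
    """Instruction to splice one tandem element into a gene's window.

    ``distance_upstream`` places the element's 5'-most base that many nt
    before the anchor end of the window (1-based from the right).
    """

    gene_id: str
    element_string: str
    distance_upstream: int
    anchor_kind: str = "AUG"

    def __post_init__(self):
        if self.anchor_kind not in ("TSS", "AUG"):
            raise ValueError("anchor_kind must be 'TSS' or 'AUG'")
        if len(find_cores(self.element_string)) < 2:
            raise ValueError(
                f"element for {self.gene_id!r} must contain at least two TGAC cores"
            )
        if self.distance_upstream < len(self.element_string):
            raise ValueError(
                f"distance_upstream must be >= element length for {self.gene_id!r}"
            )


def _base_probs(gc_fraction: float) -> np.ndarray:
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    gc = gc_fraction / 2.0
    at = (1.0 - gc_fraction) / 2.0
    return np.array([at, gc, gc, at])  # a, c, g, t


def _find_forbidden(seq_upper: str) -> list[int]:
    pos = []
    for pat in _FORBIDDEN:
        i = seq_upper.find(pat)
        while i != -1:
            pos.append(i)
            i = seq_upper.find(pat, i + 1)
    return sorted(pos)


def generate_corefree_background(
    length: int,
    gc_fraction: float = 0.36,
    seed: int | None = 0,
    *,
    rng: np.random.Generator | None = None,
) -> str:
    """Random lowercase background guaranteed free of TGAC cores on either strand.

    Rejection sampling: offending 4-nt windows are redrawn until the string
    contains neither ``TGAC`` nor ``GTCA``.  Deterministic for a fixed seed.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    probs = _base_probs(gc_fraction)
    if rng is None:
        rng = np.random.default_rng(seed)
    arr = _BASES[rng.choice(4, size=length, p=probs)]
    while True:
        seq = arr.tobytes().decode("ascii")
        offending = _find_forbidden(seq.upper())
        if not offending:
            return seq
        for i in offending:
            arr[i : i + 4] = _BASES[rng.choice(4, size=min(4, length - i), p=probs)]


def _splice(background: str, plans: list[EmbedPlan], window_length: int) -> tuple[str, list[tuple[int, int]]]:
    """Replace background stretches with the planned elements; return spans."""
    spans = []
    for p in plans:
        start = window_length - p.distance_upstream
        if start < 0:
            raise ValueError(
                f"plan for {p.gene_id!r} does not fit: distance {p.distance_upstream} "
                f"> window {window_length}"
            )
        spans.append((start, start + len(p.element_string)))
    for (s1, e1), (s2, e2) in zip(sorted(spans), sorted(spans)[1:]):
        if s2 < e1:
            raise ValueError("embedded elements overlap within one gene")
    chars = list(background)
    for p, (s, e) in zip(plans, spans):
        chars[s:e] = list(p.element_string)
    return "".join(chars), spans


def _expected_hits(plans: list[EmbedPlan], spans: list[tuple[int, int]]) -> set[tuple[int, int, str]]:
    hits = set()
    for p, (s, _) in zip(plans, spans):
        for h in find_cores(p.element_string):
            hits.add((s + h.start, h.length, h.strand))
    return hits


def _fix_junctions(
    seq: str,
    plans: list[EmbedPlan],
    spans: list[tuple[int, int]],
    gc_fraction: float,
    rng: np.random.Generator,
    max_rounds: int = 200,
) -> str:
    """Redraw background bases until the window's cores are exactly the planned ones.

    Splicing can create incidental cores spanning a junction, or extend an
    element's terminal core (a background ``T`` before an element starting
    ``TGAC``, or ``A`` after one ending ``GTCA``), which would shift the
    reported coordinates.  Any hit not in the expected set has its
    outside-element bases redrawn.
    """
    expected = _expected_hits(plans, spans)
    in_span = [False] * len(seq)
    for s, e in spans:
        for i in range(s, e):
            in_span[i] = True
    probs = _base_probs(gc_fraction)
    chars = list(seq)
    for _ in range(max_rounds):
        observed = {(h.start, h.length, h.strand) for h in find_cores("".join(chars))}
        bad = observed - expected
        if not bad and not (expected - observed):
            return "".join(chars)
        if not bad:  # planned element destroyed with nothing left to redraw
            raise RuntimeError("embedded element lost during junction repair")
        # A bad hit is either an incidental junction core or a planned core
        # whose maximality was changed by a flanking background base; in both
        # cases redrawing the hit's outside-element bases repairs it.
        for start, length, _ in bad:
            for i in range(start, start + length):
                if 0 <= i < len(chars) and not in_span[i]:
                    chars[i] = chr(_BASES[rng.choice(4, p=probs)])
    raise RuntimeError("junction repair did not converge")


def build_promoter_set(
    plans: list[EmbedPlan],
    window_length: int = 2000,
    gc_fraction: float = 0.36,
    seed: int = 0,
    *,
    background_genes: tuple[str, ...] = (),
) -> tuple[dict[str, str], pd.DataFrame]:
    """Build core-free windows with embedded elements and an exact truth table.

    Returns ``(windows, truth)``: a gene_id -> sequence mapping and a table
    with one row per embedded element (gene_id, element_string, distance,
    anchor, orientation and linker as scanned from the bare element).  Genes
    listed in ``background_genes`` (and any plan-less gene) receive pure
    background.  The scanner applied to any window recovers exactly the
    planned dyads — no more, no fewer.
    """
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    rng = np.random.default_rng(seed)
    by_gene: dict[str, list[EmbedPlan]] = {}
    for p in plans:
        by_gene.setdefault(p.gene_id, []).append(p)
    for g in background_genes:
        by_gene.setdefault(g, [])
    windows: dict[str, str] = {}
    rows = []
    for gene_id, gene_plans in by_gene.items():
        bg = generate_corefree_background(window_length, gc_fraction, rng=rng)
        if gene_plans:
            seq, spans = _splice(bg, gene_plans, window_length)
            seq = _fix_junctions(seq, gene_plans, spans, gc_fraction, rng)
        else:
            seq = bg
        windows[gene_id] = seq
        for p in gene_plans:
            dyads = scan_sequence(p.element_string)
            rows.append(
                {
                    "gene_id": gene_id,
                    "element_string": p.element_string,
                    "distance": p.distance_upstream,
                    "anchor": p.anchor_kind,
                    "orientation": dyads[0].orientation if dyads else None,
                    "linker_length": dyads[0].linker_length if dyads else None,
                }
            )
    truth = pd.DataFrame(
        rows,
        columns=["gene_id", "element_string", "distance", "anchor", "orientation", "linker_length"],
    )
    return windows, truth


def write_windows_fasta(windows: dict[str, str], path: str | Path) -> None:
    """Write windows as FASTA, one record per gene."""
    with open(path, "w") as fh:
        for gene_id, seq in windows.items():
            fh.write(f">{gene_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def write_promoter_genome(
    windows: dict[str, str],
    fasta_path: str | Path,
    gff_path: str | Path,
    *,
    body_length: int = 90,
    gc_fraction: float = 0.36,
    seed: int = 0,
    minus_strand: tuple[str, ...] = (),
) -> None:
    """Materialise windows as a synthetic genome FASTA plus companion GFF3.

    Each gene gets its own contig consisting of the window followed by a
    core-free ``body_length``-nt gene body; the gene/mRNA/CDS feature starts
    immediately after the window, so extracting a window-length upstream
    region (either anchor) returns the window exactly.  Contigs named in
    ``minus_strand`` are reverse-complemented and annotated on ``-``.
    """
    rng = np.random.default_rng(seed)
    with open(fasta_path, "w") as fa, open(gff_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for gene_id, window in windows.items():
            body = generate_corefree_background(body_length, gc_fraction, rng=rng)
            contig = window + body
            # Re-check the window/body junction: the body must not create a
            # core or extend a window hit across the boundary.
            guard = 0
            while {(h.start, h.length, h.strand) for h in find_cores(contig)} != {
                (h.start, h.length, h.strand) for h in find_cores(window)
            }:
                body = generate_corefree_background(body_length, gc_fraction, rng=rng)
                contig = window + body
                guard += 1
                if guard > 100:
                    raise RuntimeError("could not build a clean gene body")
            n = len(contig)
            if gene_id in minus_strand:
                contig_out = _revcomp(contig)
                g_start, g_end, strand = 1, body_length, "-"
            else:
                contig_out = contig
                g_start, g_end, strand = len(window) + 1, n, "+"
            contig_name = f"chr_{gene_id}"
            fa.write(f">{contig_name}\n")
            for i in range(0, n, 70):
                fa.write(contig_out[i : i + 70] + "\n")
            gff.write(f"##sequence-region {contig_name} 1 {n}\n")
            common = f"{contig_name}\tbeldyad\t"
            gff.write(common + f"gene\t{g_start}\t{g_end}\t.\t{strand}\t.\tID={gene_id}\n")
            gff.write(
                common
                + f"mRNA\t{g_start}\t{g_end}\t.\t{strand}\t.\tID={gene_id}.1;Parent={gene_id}\n"
            )
            gff.write(
                common
                + f"CDS\t{g_start}\t{g_end}\t.\t{strand}\t0\tID={gene_id}.cds;Parent={gene_id}.1\n"
            )


@dataclass(frozen=True)
class QpcrSimSpec:
    """Specification for a simulated replicate qPCR experiment.

    ``true_fold_change`` is the linear expression ratio transgenic/WT per
    gene (WT is the calibrator, fold change 1 by construction);
    ``ct_noise_sd`` is Gaussian cycle noise applied independently to every
    target and reference Ct measurement.
    """

    genes: tuple[str, ...]
    true_fold_change: dict[str, float] = field(default_factory=dict)
    n_replicates: int = 3
    ct_noise_sd: float = 0.3
    reference_gene: str = "StActin8"
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        for g, fc in self.true_fold_change.items():
            if not (fc > 0 and math.isfinite(fc)):
                raise ValueError(f"fold change for {g!r} must be a positive finite real")


def simulate_ct_table(spec: QpcrSimSpec) -> pd.DataFrame:
    """Simulate a replicate Ct table under the inverse Livak model.

    For each gene/condition/replicate the target Ct is
    ``baseline - log2(expression) + N(0, sd)`` with expression 1 in WT and
    the true fold change in the transgenic condition; the reference-gene Ct
    is condition-independent.  Columns: gene, condition, replicate,
    target_ct, reference_ct.
    """
    rng = np.random.default_rng(spec.seed)
    ref_base = rng.uniform(16.0, 20.0)
    rows = []
    for gene in spec.genes:
        base = rng.uniform(22.0, 28.0)
        fc = spec.true_fold_change.get(gene, 1.0)
        if not fc > 0:
            raise ValueError("fold change must be positive")
        for condition, expr in (("WT", 1.0), ("transgenic", fc)):
            for rep in range(1, spec.n_replicates + 1):
                rows.append(
                    {
                        "gene": gene,
                        "condition": condition,
                        "replicate": rep,
                        "target_ct": base - math.log2(expr) + rng.normal(0.0, spec.ct_noise_sd),
                        "reference_ct": ref_base + rng.normal(0.0, spec.ct_noise_sd),
                    }
                )
    return pd.DataFrame(rows)
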