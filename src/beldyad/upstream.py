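"""Extraction of strand-aware upstream windows from a genome FASTA + GFF3.

Coordinates are GFF3-style 1-based inclusive throughout; the only
0-based/slice conversion happens inside :meth:`Genome.fetch`.  Anchors:
``TSS`` is the 5' end of the gene/mRNA feature, ``AUG`` the 5' end of the
first CDS segment in gene orientation.  The returned window is written
5'->3' in gene orientation, its rightmost base immediately adjacent to the
anchor, so a downstream scanner's ``distance_upstream`` (counted 1-based
from the right) is directly "nt upstream of the anchor".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import gffutils
from pyfaidx import Fasta

from .synthetic import _revcomp

__all__ = ["Genome", "GeneModel", "UpstreamRegion", "load_genome", "read_gene_models", "extract_upstream"]


class Genome:
    """Random-access view of an indexed FASTA (1-based inclusive fetches)."""

    def __init__(self, path: str | Path):
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        # pyfaidx itself rejects duplicate record ids while indexing.
        self._fasta = Fasta(str(path), sequence_always_upper=False)

    def __contains__(self, contig: str) -> bool:
        return contig in self._fasta

    def contigs(self) -> list[str]:
        return list(self._fasta.keys())

    def length(self, contig: str) -> int:
        return len(self._fasta[contig])

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Subsequence at 1-based inclusive [start, end]."""
        if contig not in self._fasta:
            raise KeyError(f"no contig {contig!r}")
        n = len(self._fasta[contig])
        if not (1 <= start <= end <= n):
            raise ValueError(
                f"coordinates [{start}, {end}] out of range for {contig!r} (length {n})"
            )
        return str(self._fasta[contig][start - 1 : end])


def load_genome(path: str | Path) -> Genome:
    """Open a FASTA file for random access; duplicate record ids are rejected."""
    return Genome(path)


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model: span, strand and (optionally) the CDS 5' end."""

    gene_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    cds_start: int | None = None  # genomic coordinate of the CDS 5'-most base


def read_gene_models(gff_path: str | Path) -> list[GeneModel]:
    """Read gene features (with CDS anchors where present) from a GFF3 file."""
    db = gffutils.create_db(
        str(gff_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models = []
    for gene in db.features_of_type("gene"):
        cds = list(db.children(gene, featuretype="CDS"))
        cds_start: int | None = None
        if cds:
            cds_start = min(c.start for c in cds) if gene.strand == "+" else max(c.end for c in cds)
        gene_id = gene.attributes.get("ID", [gene.id])[0]
        models.append(
            GeneModel(
                gene_id=gene_id,
                contig=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                cds_start=cds_start,
            )
        )
    return models


@dataclass(frozen=True)
class UpstreamRegion:
    """A gene's upstream window, 5'->3' in gene orientation.

    ``sequence`` may be shorter than ``window_length`` when the gene sits
    near a contig edge.  ``source_start``/``source_end`` are the 1-based
    inclusive genomic coordinates of the window on the reference strand.
    """

    gene_id: str
    anchor_kind: str
    window_length: int
    sequence: str
    source_contig: str
    source_start: int
    source_end: int
    source_strand: str


def extract_upstream(
    genome: Genome,
    gene: GeneModel,
    anchor_kind: str = "TSS",
    window_length: int = 2000,
) -> UpstreamRegion:
    """Extract the upstream window of a gene, reverse-complemented for ``-`` genes.

    For a plus-strand gene the window is the ``window_length`` bases left of
    the anchor, reported as-is; for a minus-strand gene the bases right of
    the anchor, reverse-complemented.  Windows truncated at a contig edge
    raise a warning, not an error.
    """
    if anchor_kind not in ("TSS", "AUG"):
        raise ValueError("anchor_kind must be 'TSS' or 'AUG'")
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    if anchor_kind == "AUG":
        if gene.cds_start is None:
            raise ValueError(f"gene {gene.gene_id!r} has no CDS; cannot anchor at AUG")
        anchor = gene.cds_start
    else:
        anchor = gene.start if gene.strand == "+" else gene.end
    clen = genome.length(gene.contig)
    if gene.strand == "+":
        start = max(1, anchor - window_length)
        end = anchor - 1
        seq = genome.fetch(gene.contig, start, end) if end >= start else ""
    elif gene.strand == "-":
        start = anchor + 1
        end = min(clen, anchor + window_length)
        seq = _revcomp(genome.fetch(gene.contig, start, end)) if end >= start else ""
        if end < start:
            start, end = anchor + 1, anchor  # degenerate, zero-length
    else:
        raise ValueError(f"gene {gene.gene_id!r} has no usable strand")
    if len(seq) < window_length:
        warnings.warn(
            f"upstream window of {gene.gene_id!r} truncated to {len(seq)} nt at a contig edge",
            stacklevel=2,
        )
    return UpstreamRegion(
        gene_id=gene.gene_id,
        anchor_kind=anchor_kind,
        window_length=window_length,
        sequence=seq,
        source_contig=gene.contig,
        source_start=start if seq else anchor,
        source_end=end if seq else anchor,
        source_strand=gene.strand,
    )
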