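"""Tabular and interval output for dyad scans.

Dyads are reported as TSV (one row per dyad), BED6 (window-relative, 0-based
half-open, name = orientation) and GFF3 (genome-relative when the scanned
region carries source coordinates).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .scan import DyadElement
from .upstream import UpstreamRegion

__all__ = ["dyads_to_frame", "write_dyads_tsv", "write_dyads_bed", "write_dyads_gff3"]


def dyads_to_frame(dyads: Iterable[DyadElement], sequences: dict[str, str] | None = None) -> pd.DataFrame:
    """One row per dyad; ``sequences`` (gene_id -> window) adds element text."""
    rows = []
    for d in dyads:
        element = None
        if sequences is not None and d.gene_id in sequences:
            element = d.element_text(sequences[d.gene_id])
        rows.append(
            {
                "gene_id": d.gene_id,
                "element": element,
                "orientation": d.orientation,
                "linker_length": d.linker_length,
                "linker_text": d.linker_text,
                "distance_upstream": d.distance_upstream,
                "left_start": d.left.start,
                "left_length": d.left.length,
                "left_strand": d.left.strand,
                "right_start": d.right.start,
                "right_length": d.right.length,
                "right_strand": d.right.strand,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "element",
            "orientation",
            "linker_length",
            "linker_text",
            "distance_upstream",
            "left_start",
            "left_length",
            "left_strand",
            "right_start",
            "right_length",
            "right_strand",
        ],
    )


def write_dyads_tsv(dyads: Iterable[DyadElement], path: str | Path, **kwargs) -> None:
    dyads_to_frame(dyads, **kwargs).to_csv(path, sep="\t", index=False)


def write_dyads_bed(dyads: Iterable[DyadElement], path: str | Path) -> None:
    """Window-relative BED6; the dyad has no single strand, so '.' is used."""
    with open(path, "w") as fh:
        for d in dyads:
            fh.write(f"{d.gene_id}\t{d.start}\t{d.end}\t{d.orientation}\t0\t.\n")


def write_dyads_gff3(
    per_region: Sequence[tuple[UpstreamRegion, Sequence[DyadElement]]],
    path: str | Path,
) -> None:
    """Genome-relative GFF3 for dyads found in extracted upstream regions.

    Window offsets are mapped back through the region's source coordinates
    (reverse-complement aware for minus-strand genes).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for region, dyads in per_region:
            for k, d in enumerate(dyads, 1):
                if region.source_strand == "+":
                    g_start = region.source_start + d.start
                    g_end = region.source_start + d.end - 1
                else:
                    g_end = region.source_end - d.start
                    g_start = region.source_end - (d.end - 1)
                attrs = (
                    f"ID={region.gene_id}.dyad{k};orientation={d.orientation};"
                    f"linker_length={d.linker_length};distance_upstream={d.distance_upstream}"
                )
                fh.write(
                    f"{region.source_contig}\tbeldyad\tnucleotide_motif\t{g_start}\t{g_end}"
                    f"\t.\t{region.source_strand}\t.\t{attrs}\n"
                )
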