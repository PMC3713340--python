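"""Literature-curated tandem TGAC-core elements of potato StBEL5/POTH1 targets.

Two published element sets are transcribed here verbatim (uppercase cores,
lowercase linkers, as printed):

* :data:`TARGET_GENE_ELEMENTS` — tandem elements found upstream of hormone
  pathway genes targeted by StBEL5 (auxin transport ``PIN``/``LAX`` genes,
  auxin synthesis ``YUCCA1`` genes, ``GA2ox1``, ``IPT``, ``ARF8``, the MADS
  box gene ``AGL8``/POTM1-1, and the auto-regulated ``StBEL5`` promoter
  itself).  Distances are nt upstream of the stated anchor (TSS or AUG).
* :data:`AUX_IAA_ELEMENTS` — the survey of all 27 non-redundant potato
  AUX/IAA genes; 14 carry a tandem element in their upstream sequence.
  Distances are base pairs from the AUG.

The published ARF16 row gives only the two cores and a 20-nt spacing, not the
linker sequence; a synthetic core-free 20-nt linker is substituted so the row
can participate in embedding experiments (``linker_synthetic=True``; its
linker text carries no biological meaning).

The gel-shift (EMSA) probe oligonucleotides are included as scanner inputs
only; both strands of each duplex are listed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .scan import DEFAULT_MAX_LINKER, DyadElement, scan_sequence

__all__ = [
    "CatalogElement",
    "TARGET_GENE_ELEMENTS",
    "AUX_IAA_ELEMENTS",
    "AUX_IAA_GENE_COUNT",
    "GEL_SHIFT_OLIGOS",
    "INDUCED_AUX_IAA",
    "NO_MOTIF_AUX_IAA",
    "element_dyads",
    "catalog_frame",
]


@dataclass(frozen=True)
class CatalogElement:
    """One curated tandem element (or a surveyed gene without one)."""

    gene: str
    element: str | None
    orientation: str | None
    distance: int | None
    anchor: str | None
    number: int | None = None  # survey index for the AUX/IAA set
    locus: str | None = None  # PGSC gene identifier
    linker_synthetic: bool = False


#: Tandem elements upstream of StBEL5 target genes (hormone pathway survey).
#: Genes with two printed elements (StPIN1, IPT) contribute one entry each.
TARGET_GENE_ELEMENTS: tuple[CatalogElement, ...] = (
    CatalogElement("StBEL5", "GTCAAtgcTTGAC", "HtH", 820, "TSS"),
    CatalogElement("StPIN1", "TTGACactgagtttttcgattGTCAA", "TtT", 1249, "AUG"),
    CatalogElement("StPIN1", "TTGACctacatacaatctGTCAA", "TtT", 914, "AUG"),
    CatalogElement("StPIN2", "GTCActatGTCAA", "HtT", 1343, "AUG"),
    CatalogElement("StPIN4", "TGACactttcaGTCA", "TtT", 486, "AUG"),
    CatalogElement("StGA2ox1", "TTGACaaGTCA", "TtT", 1768, "AUG"),
    CatalogElement("YUCCA1a", "TTGACcttaTTGAC", "TtH", 641, "AUG"),
    CatalogElement("YUCCA1c", "TGACTTGAC", "TtH", 651, "AUG"),
    CatalogElement("IPT", "TTGACaaGTCA", "TtT", 1408, "AUG"),
    CatalogElement("IPT", "GTCAAtgcaTGAC", "HtH", 568, "AUG"),
    CatalogElement("LAX1", "TTGACttttgatctTTGAC", "TtH", 922, "AUG"),
    CatalogElement("LAX4", "TTGACTGAC", "TtH", 2629, "AUG"),
    CatalogElement("ARF8", "GTCAActccacaatGTCA", "HtT", 138, "AUG"),
    CatalogElement("AGL8", "GTCAttttcttcaatttgtctcgcttgtGTCA", "HtT", 1990, "TSS"),
)

# Synthetic core-free stand-in for the unprinted 20-nt ARF16 linker.
_ARF16_SYNTHETIC_LINKER = "catcatcatcatcatcatca"

#: Survey of the 27 non-redundant potato AUX/IAA genes (plus the StBEL5
#: promoter element in the same distance convention).  ``element`` is None
#: for surveyed genes without a tandem element.
AUX_IAA_ELEMENTS: tuple[CatalogElement, ...] = (
    CatalogElement("StIAA1", "GTCAActtGTCA", "HtT", 1546, "AUG", 1, "PGSC0003DMG400016317"),
    CatalogElement("StIAA2", None, None, None, None, 2, "PGSC0003DMG400020139"),
    CatalogElement("StIAA3", "TTGACTTGAC", "TtH", 1394, "AUG", 3, "PGSC0003DMT400049677"),
    CatalogElement("StIAA4", None, None, None, None, 4, "PGSC0003DMG400006393"),
    CatalogElement("StIAA5", None, None, None, None, 5, "PGSC0003DMG400029339"),
    CatalogElement("StIAA6", "TGACctaatTTGAC", "TtH", 2524, "AUG", 6, "PGSC0003DMG400002550"),
    CatalogElement("StIAA7", None, None, None, None, 7, "PGSC0003DMG400016280"),
    CatalogElement("StIAA8", None, None, None, None, 8, "PGSC0003DMG402002635"),
    CatalogElement("StIAA9", "TGACttattgcTTGAC", "TtH", 1674, "AUG", 9, "PGSC0003DMG402019457"),
    CatalogElement("StIAA10", None, None, None, None, 10, "PGSC0003DMG400005327"),
    CatalogElement("StIAA11", None, None, None, None, 11, "PGSC0003DMG400002636"),
    CatalogElement("StIAA12", "TTGACataacaaTTGAC", "TtH", 794, "AUG", 12, "PGSC0003DMG400013445"),
    CatalogElement("StIAA13", None, None, None, None, 13, "PGSC0003DMG400005794"),
    CatalogElement("StIAA14", "GTCAtGTCAA", "HtT", 2091, "AUG", 14, "PGSC0003DMG400002608"),
    CatalogElement("StIAA15", "TGACtctaagacatTTGAC", "TtH", 1873, "AUG", 15, "PGSC0003DMG400000118"),
    CatalogElement("StIAA16", "GTCAcTTGAC", "HtH", 2233, "AUG", 16, "PGSC0003DMG400016512"),
    CatalogElement("StIAA17", "GTCAtttagattTTGAC", "HtH", 1152, "AUG", 17, "PGSC0003DMG400005338"),
    CatalogElement("StIAA18", "TTGACacatttgaTGAC", "TtH", 992, "AUG", 18, "PGSC0003DMG400020478"),
    CatalogElement("StIAA19", None, None, None, None, 19, "PGSC0003DMG400030896"),
    CatalogElement("StIAA20", None, None, None, None, 20, "PGSC0003DMG400043142"),
    CatalogElement("StIAA21", None, None, None, None, 21, "PGSC0003DMG400013765"),
    CatalogElement("StIAA22", "GTCAAttaaTTGAC", "HtH", 712, "AUG", 22, "PGSC0003DMG400008586"),
    CatalogElement("StIAA23", None, None, None, None, 23, "PGSC0003DMG400006108"),
    CatalogElement("StIAA24", "TGACaatacataagaaGTCAA", "TtT", 667, "AUG", 24, "PGSC0003DMG400006093"),
    CatalogElement("StIAA25", "TTGACattTTGAC", "TtH", 2319, "AUG", 25, "PGSC0003DMG400001498"),
    CatalogElement("StIAA26", None, None, None, None, 26, "PGSC0003DMG400000375"),
    CatalogElement(
        "StIAA27",
        "GTCAA" + _ARF16_SYNTHETIC_LINKER + "GTCAA",
        "HtT",
        2235,
        "AUG",
        27,
        "PGSC0003DMG400021560",
        linker_synthetic=True,
    ),
    CatalogElement("StBEL5", "GTCAAtgcTTGAC", "HtH", 970, "AUG", None, "PGSC0003DMG400005930"),
)

#: Number of genes in the AUX/IAA survey proper (the StBEL5 row is extra).
AUX_IAA_GENE_COUNT = 27

#: The four AUX/IAA genes induced in roots accumulating mobile StBEL5 RNA,
#: keyed by survey index, and the two motif-free negative controls.
INDUCED_AUX_IAA: dict[str, int] = {"StIAA3": 3, "StIAA14": 14, "StIAA22": 22, "StIAA24": 24}
NO_MOTIF_AUX_IAA: dict[str, int] = {"StIAA4": 4, "StIAA5": 5}

#: EMSA probe oligos (both strands of each duplex), scanner inputs only.
GEL_SHIFT_OLIGOS: dict[str, str] = {
    "YUCCA1cS": "AAAAAATTACAAATAAATGACTTGACTAATGTTGTTATTAATCTCCACA",
    "YUCCA1cA": "TGTGGAGATTAATAACAACATTAGTCAAGTCATTTATTTGTAATTTTTT",
    "IPTS": "TTTTTTTTTGGTTTTAAGTTTGACAAGTCAGGTCTAATTTGACATCCTT",
    "IPTA": "AGGATGTCAAATTAGACCTGACTTGTCAAACTTAAAACCAAAAAAAAA",
    "PIN1Fw": "GTCTGTGTATGATTTTGACCTACATACAATCTGTCAACTAATGTGTATGA",
    "PIN1Rv": "TCATACACATTAGTTGACAGATTGTATGTAGGTCAAAATCATACACAGAC",
    "PIN2Fw": "AAATGTGAAAGTCACTATGTCAATCATTATTT",
    "PIN2Rv": "AAATAATGATTGACATAGTGACTTTCACATTT",
}


def element_dyads(element: str, max_linker: int = DEFAULT_MAX_LINKER) -> list[DyadElement]:
    """Scan a bare element/oligo string and return its dyads."""
    return scan_sequence(element, max_linker)


def catalog_frame(elements=None) -> pd.DataFrame:
    """Tabulate a catalog (default: the target-gene set) with scanned dyads.

    One row per detected dyad, carrying both the transcribed annotation and
    the scanner's own orientation/linker call so the two can be compared.
    """
    if elements is None:
        elements = TARGET_GENE_ELEMENTS
    rows = []
    for entry in elements:
        if entry.element is None:
            rows.append(
                {
                    "gene": entry.gene,
                    "element": None,
                    "annotated_orientation": None,
                    "scanned_orientation": None,
                    "linker_length": None,
                    "distance": None,
                    "anchor": None,
                }
            )
            continue
        for d in element_dyads(entry.element):
            rows.append(
                {
                    "gene": entry.gene,
                    "element": entry.element,
                    "annotated_orientation": entry.orientation,
                    "scanned_orientation": d.orientation,
                    "linker_length": d.linker_length,
                    "distance": entry.distance,
                    "anchor": entry.anchor,
                }
            )
    return pd.DataFrame(rows)
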