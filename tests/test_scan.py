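"""Scanner unit and property tests: core finding, pairing, orientation."""

import pytest
from hypothesis import given, settings, strategies as st

from beldyad.elements import (
    AUX_IAA_ELEMENTS,
    GEL_SHIFT_OLIGOS,
    TARGET_GENE_ELEMENTS,
    element_dyads,
)
from beldyad.scan import (
    classify_orientation,
    find_cores,
    pair_cores,
    scan_sequence,
)

from conftest import all_sequences, dyad_key, ref_dyads, ref_find_cores

dna = st.text(alphabet="ACGT", min_size=0, max_size=60)
dna_with_ambiguity = st.text(alphabet="ACGTNacgtn", min_size=0, max_size=60)

_REVCOMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_REVCOMP)[::-1]


class TestFindCores:
    def test_adjacent_cores_with_five_mer_extension(self):
        hits = find_cores("TGACTTGAC")
        assert [(h.start, h.length, h.strand, h.text) for h in hits] == [
            (0, 4, "+", "TGAC"),
            (4, 5, "+", "TTGAC"),
        ]

    def test_no_cores(self):
        assert find_cores("AAAACCCC") == []
        assert find_cores("") == []

    def test_minus_strand_hits_in_probe_oligo(self):
        hits = find_cores(GEL_SHIFT_OLIGOS["PIN2Fw"])
        assert [(h.text, h.strand, h.start) for h in hits] == [
            ("GTCA", "-", 10),
            ("GTCAA", "-", 18),
        ]

    def test_case_insensitive_text_preserves_input_case(self):
        hits = find_cores("ttgacaagtca")
        assert [h.text for h in hits] == ["ttgac", "gtca"]

    def test_ambiguity_codes_never_match(self):
        assert find_cores("TGNC" * 5) == []
        # an N flank must not be taken as a maximality extension
        (hit,) = find_cores("NTGACN")
        assert (hit.start, hit.length) == (1, 4)


class TestOrientation:
    @pytest.mark.parametrize(
        "left,right,label",
        [("-", "+", "HtH"), ("+", "+", "TtH"), ("+", "-", "TtT"), ("-", "-", "HtT")],
    )
    def test_mapping(self, left, right, label):
        assert classify_orientation(left, right) == label

    def test_invalid_strand_rejected(self):
        with pytest.raises(ValueError):
            classify_orientation("+", "x")


class TestPairCores:
    def test_single_core_yields_nothing(self):
        assert pair_cores(find_cores("TTGAC")) == []

    def test_zero_linker_dyad(self):
        (d,) = pair_cores(find_cores("TGACTTGAC"))
        assert d.linker_length == 0 and d.orientation == "TtH"

    def test_all_pairs_in_three_core_probe(self):
        dyads = pair_cores(find_cores(GEL_SHIFT_OLIGOS["IPTS"]), 24)
        assert sorted(d.linker_length for d in dyads) == [2, 8, 14]

    def test_adjacent_only_mode(self):
        cores = find_cores(GEL_SHIFT_OLIGOS["IPTS"])
        dyads = pair_cores(cores, 24, adjacent_only=True)
        assert sorted(d.linker_length for d in dyads) == [2, 8]

    def test_max_linker_cutoff(self):
        cores = find_cores("TTGACaaaTTGAC")  # linker 3
        assert pair_cores(cores, 2) == []
        assert len(pair_cores(cores, 3)) == 1


class TestCuratedElements:
    """Every curated element reproduces its annotated orientation."""

    @pytest.mark.parametrize(
        "entry", [e for e in TARGET_GENE_ELEMENTS], ids=lambda e: f"{e.gene}@{e.distance}"
    )
    def test_target_gene_orientations(self, entry):
        (d,) = element_dyads(entry.element)
        assert d.orientation == entry.orientation

    @pytest.mark.parametrize(
        "entry",
        [e for e in AUX_IAA_ELEMENTS if e.element is not None],
        ids=lambda e: e.gene,
    )
    def test_aux_iaa_orientations(self, entry):
        (d,) = element_dyads(entry.element)
        assert d.orientation == entry.orientation

    def test_published_linker_statements(self):
        linkers = {}
        for e in TARGET_GENE_ELEMENTS:
            (d,) = element_dyads(e.element)
            linkers[(e.gene, e.distance)] = d.linker_length
        values = list(linkers.values())
        assert max(values) == 24  # AGL8
        assert min(v for v in values if v > 0) == 2
        assert linkers[("YUCCA1c", 651)] == 0 and linkers[("LAX4", 2629)] == 0

    def test_probe_linkers(self):
        (pin1,) = element_dyads(GEL_SHIFT_OLIGOS["PIN1Fw"])
        assert pin1.linker_length == 13
        (pin2,) = element_dyads(GEL_SHIFT_OLIGOS["PIN2Fw"])
        assert pin2.linker_length == 4
        ipt = element_dyads(GEL_SHIFT_OLIGOS["IPTS"])
        assert min(d.linker_length for d in ipt) == 2

    def test_probe_reverse_strands_mirror_forward(self):
        for fw, rv in [("PIN1Fw", "PIN1Rv"), ("PIN2Fw", "PIN2Rv")]:
            f = {d.linker_length for d in element_dyads(GEL_SHIFT_OLIGOS[fw])}
            r = {d.linker_length for d in element_dyads(GEL_SHIFT_OLIGOS[rv])}
            assert f == r


class TestScanSequence:
    def test_distance_conventions(self):
        seq = "A" * 10 + "TGACTTGAC" + "A" * 5  # dyad at offsets 10..19, window 24
        (d5,) = scan_sequence(seq)
        assert d5.distance_upstream == 24 - 10
        (d3,) = scan_sequence(seq, distance_to="3p")
        assert d3.distance_upstream == 24 - 19 + 1

    def test_short_windows_yield_nothing(self):
        for n in range(8):
            assert scan_sequence("TGACTGA"[:n]) == []


class TestOracleEquivalence:
    """The scanner equals a naive reference on exhaustive + random inputs."""

    @pytest.mark.parametrize("length", range(1, 9))
    def test_exhaustive_small(self, length):
        for seq in all_sequences(length):
            got = {dyad_key(d) for d in pair_cores(find_cores(seq), 24, sequence=seq)}
            assert got == ref_dyads(seq, 24), seq

    def test_random_long(self, random_dna, rng):
        for _ in range(4000):
            n = int(rng.integers(9, 61))
            seq = random_dna(n)
            max_linker = int(rng.integers(0, 25))
            got = {dyad_key(d) for d in pair_cores(find_cores(seq), max_linker, sequence=seq)}
            assert got == ref_dyads(seq, max_linker), (seq, max_linker)


class TestProperties:
    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(dna_with_ambiguity)
    def test_maximal_cores_never_overlap(self, seq):
        hits = find_cores(seq)
        for a, b in zip(hits, hits[1:]):
            assert a.end <= b.start

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(dna, st.integers(min_value=0, max_value=24))
    def test_reverse_complement_symmetry(self, seq, max_linker):
        """Scanning the reverse complement swaps left/right, keeps linkers,
        and maps orientations HtH<->HtH, TtT<->TtT, HtT<->TtH."""
        fwd = pair_cores(find_cores(seq), max_linker)
        rev = pair_cores(find_cores(revcomp(seq)), max_linker)
        n = len(seq)
        mapped = {
            (n - d.right.end, n - d.left.start, d.linker_length,
             {"HtH": "HtH", "TtT": "TtT", "HtT": "TtH", "TtH": "HtT"}[d.orientation])
            for d in fwd
        }
        got = {(d.left.start, d.right.end, d.linker_length, d.orientation) for d in rev}
        assert got == mapped

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(dna)
    def test_linker_text_consistent(self, seq):
        for d in pair_cores(find_cores(seq), 24, sequence=seq):
            assert len(d.linker_text) == d.linker_length
            assert seq[d.left.end : d.right.start] == d.linker_text
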