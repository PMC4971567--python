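"""Transcript model, database I/O, default-transcript selection and
genomic<->c. coordinate mapping."""

import numpy as np
import pytest

from opexlite.fixtures import random_transcript
from opexlite.transcripts import (
    Transcript,
    TranscriptIndex,
    TranscriptParseError,
    TranscriptValidationError,
    filter_gene_candidates,
    genomic_to_csn,
    load_transcript_db,
    overlapping_transcripts,
    region_to_csn_label,
    select_default_transcript,
    write_transcript_db,
)


def make_tx(**kwargs):
    defaults = dict(
        gene_symbol="G",
        transcript_id="T",
        is_ccds=False,
        chrom="1",
        strand="+",
        exons=[(100, 200)],
        cds_start=120,
        cds_end=180,
    )
    defaults.update(kwargs)
    return Transcript(**defaults)


class TestModel:
    def test_invariants_enforced(self):
        with pytest.raises(TranscriptValidationError, match="exon end"):
            make_tx(exons=[(200, 100)], cds_start=120, cds_end=180)
        with pytest.raises(TranscriptValidationError, match="unsorted"):
            make_tx(exons=[(300, 400), (100, 200)], cds_start=150, cds_end=350)
        with pytest.raises(TranscriptValidationError, match="cds_start"):
            make_tx(cds_start=180, cds_end=120)
        with pytest.raises(TranscriptValidationError, match="outside"):
            make_tx(cds_start=50, cds_end=180)

    def test_span_includes_introns(self, toy_transcript):
        assert toy_transcript.span == (101, 400)
        assert toy_transcript.contains(250)  # intronic
        assert not toy_transcript.contains(100)
        assert not toy_transcript.contains(401)

    def test_coding_length(self, toy_transcript):
        assert toy_transcript.coding_length() == 100
        assert toy_transcript.exonic_length() == 200


class TestDatabaseIO:
    def test_round_trip_three_transcripts(self, tmp_path):
        txs = [
            make_tx(transcript_id="T1", exons=[(100, 200), (300, 400)], cds_start=150, cds_end=350),
            make_tx(transcript_id="T2", strand="-", is_ccds=True),
            make_tx(transcript_id="T3", chrom="X", is_pseudogene=True),
        ]
        path = tmp_path / "db.tsv"
        write_transcript_db(txs, str(path))
        loaded = load_transcript_db(str(path))
        assert len(loaded) == 3
        for orig, back in zip(txs, loaded):
            assert back.transcript_id == orig.transcript_id
            assert back.exons == orig.exons
            assert back.strand == orig.strand
            assert back.is_ccds == orig.is_ccds
            assert back.is_pseudogene == orig.is_pseudogene
            assert (back.cds_start, back.cds_end) == (orig.cds_start, orig.cds_end)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "db.tsv"
        write_transcript_db([make_tx()], str(path))
        with open(path, "a") as fh:
            fh.write("G\tT2\t0\t1\t+\tnot_an_int\t200\t120\t180\n")
        with pytest.raises(TranscriptParseError, match=":3"):
            load_transcript_db(str(path))

    def test_invariant_violation_names_transcript(self, tmp_path):
        path = tmp_path / "db.tsv"
        with open(path, "w") as fh:
            fh.write("GENE\tTRANSCRIPT\tCCDS\tCHROM\tSTRAND\tEXON_STARTS\tEXON_ENDS\tCDS_START\tCDS_END\n")
            fh.write("G\tTBAD\t0\t1\t+\t200\t100\t120\t180\n")  # exon end < start
        with pytest.raises(TranscriptValidationError, match="TBAD"):
            load_transcript_db(str(path))


class TestDefaultSelection:
    def test_exclusion_reasons(self):
        mt = make_tx(transcript_id="T_MT", chrom="MT")
        nostop = make_tx(transcript_id="T_NS", has_stop_codon=False)
        pseudo = make_tx(transcript_id="T_PG", is_pseudogene=True)
        ok = make_tx(transcript_id="T_OK", chrom="X")
        included, excluded = filter_gene_candidates([mt, nostop, pseudo, ok])
        assert included == [ok]
        assert {t.transcript_id: reason for t, reason in excluded} == {
            "T_MT": "chromosome",
            "T_NS": "incomplete_cds",
            "T_PG": "pseudogene",
        }

    def test_ccds_preferred(self):
        t1 = make_tx(transcript_id="T1", is_ccds=True)
        t2 = make_tx(transcript_id="T2", is_ccds=False, exons=[(100, 500)], cds_start=120, cds_end=480)
        assert select_default_transcript([t1, t2]) is t1

    def test_single_candidate(self):
        t1 = make_tx(transcript_id="T1")
        assert select_default_transcript([t1]) is t1

    def test_tie_break_longest_cds(self):
        t1 = make_tx(transcript_id="T1", is_ccds=True, cds_start=120, cds_end=160)
        t2 = make_tx(transcript_id="T2", is_ccds=True, exons=[(100, 300)], cds_start=120, cds_end=280)
        assert select_default_transcript([t1, t2]) is t2

    def test_tie_break_lexicographic_and_permutation_invariance(self):
        txs = [make_tx(transcript_id=tid) for tid in ("T3", "T1", "T2")]
        for perm in ([0, 1, 2], [2, 0, 1], [1, 2, 0]):
            assert select_default_transcript([txs[i] for i in perm]).transcript_id == "T1"

    def test_empty_is_usage_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            select_default_transcript([])

    def test_mixed_genes_rejected(self):
        with pytest.raises(ValueError, match="multiple genes"):
            select_default_transcript([make_tx(gene_symbol="A"), make_tx(gene_symbol="B")])


class TestCoordinateMapping:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            (151, "c.1"),
            (150, "c.-1"),
            (101, "c.-50"),
            (201, "c.50+1"),
            (250, "c.50+50"),  # midpoint of a 100-bp intron anchors the donor
            (251, "c.51-50"),
            (300, "c.51-1"),
            (350, "c.100"),
            (351, "c.*1"),
            (400, "c.*50"),
        ],
    )
    def test_plus_strand_examples(self, toy_transcript, pos, expected):
        assert str(genomic_to_csn(toy_transcript, pos)) == expected

    @pytest.mark.parametrize(
        "pos,expected",
        [
            # transcript order: 400..301 then 200..101; coding 350..301 then 200..151
            (350, "c.1"),
            (351, "c.-1"),
            (400, "c.-50"),
            (301, "c.50"),
            (300, "c.50+1"),  # donor side of the intron in transcript orientation
            (201, "c.51-1"),
            (151, "c.100"),
            (150, "c.*1"),
        ],
    )
    def test_minus_strand_examples(self, toy_transcript_minus, pos, expected):
        assert str(genomic_to_csn(toy_transcript_minus, pos)) == expected

    def test_out_of_range(self, toy_transcript):
        with pytest.raises(ValueError, match="outside"):
            genomic_to_csn(toy_transcript, 100)
        with pytest.raises(ValueError, match="outside"):
            genomic_to_csn(toy_transcript, 401)

    @pytest.mark.parametrize("seed", range(5))
    def test_enumeration_properties_random_transcripts(self, seed):
        """Coding c. indices over a transcript form exactly {1..L}; the
        exonic map is invertible; intronic offsets are consistent."""
        rng = np.random.default_rng(seed)
        for k in range(4):
            t = random_transcript(rng, "chr1", 50_000, transcript_id=f"T{seed}_{k}")
            lo, hi = t.span
            coding = []
            inverse = {}
            for pos in range(lo, hi + 1):
                csn = genomic_to_csn(t, pos)
                if csn.kind == "coding":
                    coding.append(csn.coding_index)
                if csn.intron_offset == 0:
                    key = (csn.anchor_kind, csn.coding_index)
                    assert key not in inverse, "exonic c. coordinates must be unique"
                    inverse[key] = pos
            L = t.coding_length()
            assert sorted(coding) == list(range(1, L + 1))
            # round trip through the enumerated inverse map
            for pos in range(lo, hi + 1):
                csn = genomic_to_csn(t, pos)
                if csn.intron_offset == 0:
                    assert inverse[(csn.anchor_kind, csn.coding_index)] == pos

    def test_strand_symmetry(self, toy_transcript, toy_transcript_minus):
        """Flipping the strand maps the old last coding base to the new c.1."""
        L = toy_transcript.coding_length()
        plus_last = toy_transcript.coding_positions()[-1]
        assert str(genomic_to_csn(toy_transcript, plus_last)) == f"c.{L}"
        assert str(genomic_to_csn(toy_transcript_minus, plus_last)) == "c.1"


class TestRegionLabels:
    def test_coding_interval(self, toy_transcript):
        assert region_to_csn_label(toy_transcript, 151, 160) == "GENE:c.1-c.10"

    def test_single_base(self, toy_transcript):
        assert region_to_csn_label(toy_transcript, 151, 151) == "GENE:c.1-c.1"

    def test_clipped_utr_interval(self, toy_transcript):
        # pos 150 is c.-1, so the base 10 positions 5' of it (pos 140) is c.-11
        assert region_to_csn_label(toy_transcript, 140, 160) == "GENE:c.-11-c.10"

    def test_minus_strand_orders_endpoints_by_transcript(self, toy_transcript_minus):
        label = region_to_csn_label(toy_transcript_minus, 301, 350)
        assert label == "GENE:c.1-c.50"

    def test_no_overlap(self, toy_transcript):
        with pytest.raises(ValueError, match="overlap"):
            region_to_csn_label(toy_transcript, 500, 600)


class TestOverlap:
    def test_intronic_position_hits(self, toy_transcript):
        assert overlapping_transcripts([toy_transcript], "chr1", 250) == [toy_transcript]

    def test_outside_span_empty(self, toy_transcript):
        assert overlapping_transcripts([toy_transcript], "chr1", 50) == []
        assert overlapping_transcripts([toy_transcript], "chr2", 250) == []

    def test_index_matches_linear_scan(self):
        rng = np.random.default_rng(42)
        db = [
            random_transcript(rng, "chr1", 100_000, transcript_id=f"T{i}")
            for i in range(20)
        ]
        index = TranscriptIndex(db)
        for pos in rng.integers(1, 100_000, size=100):
            pos = int(pos)
            expect = sorted(
                overlapping_transcripts(db, "chr1", pos),
                key=lambda t: (t.span, t.transcript_id),
            )
            assert index.at("chr1", pos) == expect
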