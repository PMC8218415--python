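"""Strand-aware C/T/N calling and call-matrix construction."""

import numpy as np
import pysam
import pytest

from ampliconmeth import (
    AmpliconDef,
    AssayType,
    CallingParams,
    CpGSite,
    build_call_matrix,
    build_locus_map,
    call_read,
    read_matrix_tsv,
    write_matrix_tsv,
)
from ampliconmeth.synthetic_data import DemethylationModel, simulate_alignments

from conftest import make_matrix

HEADER = pysam.AlignmentHeader.from_dict(
    {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chrT", "LN": 1000}]}
)


def make_read(seq, start, name="r1", quals=None, flag=0, mapq=60, tags=(("XG", "CT"),)):
    a = pysam.AlignedSegment(HEADER)
    a.query_name = name
    a.query_sequence = seq
    a.flag = flag
    a.reference_id = 0
    a.reference_start = start
    a.mapping_quality = mapq
    a.cigartuples = [(0, len(seq))]
    a.query_qualities = pysam.qualitystring_to_array(quals or "I" * len(seq))
    for tag, value in tags:
        a.set_tag(tag, value, value_type="Z")
    return a


def sites_at(*positions):
    return [
        CpGSite(chrom="chrT", pos=p, amplicon="ampT", global_index=k + 1)
        for k, p in enumerate(positions)
    ]


PARAMS = CallingParams(min_base_quality=30)


class TestCallRead:
    def test_c_and_t_bases_called_directly(self):
        # CpG cytosines at 10, 14, 18; read carries C, T, C there
        read = make_read("ACGTTTGTCG", 8)
        sites = sites_at(9, 13, 16)
        read = make_read("TCGATCGATCGA", 8)  # C at 9, 13, 17... build explicitly
        sites = sites_at(9, 13, 17)
        assert call_read(read, sites, AssayType.BS, PARAMS) == ["C", "C", "C"]

    def test_non_ct_base_is_uninformative(self):
        read = make_read("TTGA", 10)  # T at 10, A (error) at 13
        sites = sites_at(10, 13)
        assert call_read(read, sites, AssayType.BS, PARAMS) == ["T", "N"]

    def test_low_quality_base_is_masked(self):
        read = make_read("CC", 10, quals="I5")  # second base Q20 < 30
        sites = sites_at(10, 11)
        assert call_read(read, sites, AssayType.BS, PARAMS) == ["C", "N"]

    def test_uncovered_site_is_n(self):
        read = make_read("CC", 10)
        sites = sites_at(10, 50)
        assert call_read(read, sites, AssayType.BS, PARAMS) == ["C", "N"]

    def test_deletion_at_site_is_n(self):
        a = make_read("CCC", 10)
        a.cigartuples = [(0, 1), (2, 1), (0, 2)]  # 1M1D2M: ref pos 11 deleted
        sites = sites_at(10, 11)
        assert call_read(a, sites, AssayType.BS, PARAMS) == ["C", "N"]

    def test_opposite_conversion_strand_yields_all_n(self):
        read = make_read("CC", 10, tags=(("XG", "GA"),))
        sites = sites_at(10, 11)
        assert call_read(read, sites, AssayType.BS, PARAMS) == ["N", "N"]

    def test_bsmap_zs_tag_recognized(self):
        read = make_read("CC", 10, tags=(("ZS", "-+"),))
        assert call_read(read, sites_at(10, 11), AssayType.BS, PARAMS) == ["N", "N"]
        read = make_read("CC", 10, tags=(("ZS", "++"),))
        assert call_read(read, sites_at(10, 11), AssayType.BS, PARAMS) == ["C", "C"]

    def test_strand_from_flags_when_untagged(self):
        fwd = make_read("CC", 10, tags=())
        rev = make_read("CC", 10, tags=(), flag=16)
        sites = sites_at(10, 11)
        assert call_read(fwd, sites, AssayType.BS, PARAMS) == ["C", "C"]
        assert call_read(rev, sites, AssayType.BS, PARAMS) == ["N", "N"]

    def test_unmapped_read_rejected(self):
        a = make_read("CC", 10)
        a.flag = 4
        with pytest.raises(ValueError, match="unmapped"):
            call_read(a, sites_at(10), AssayType.BS, PARAMS)

    def test_raising_baseq_never_gains_information(self):
        # monotone information loss: N stays N as the threshold rises
        read = make_read("CTCT", 10, quals="I5I5")
        sites = sites_at(10, 11, 12, 13)
        lo = call_read(read, sites, AssayType.BS, CallingParams(min_base_quality=0))
        hi = call_read(read, sites, AssayType.BS, CallingParams(min_base_quality=30))
        for a, b in zip(lo, hi):
            assert b == a or b == "N"


class TestBuildCallMatrix:
    def _locus(self):
        # reference with CpGs at 12 and 16
        ref = "T" * 10 + "ACGTTCGTTT" + "T" * 20
        amp = AmpliconDef("ampT", "chrT", 10, 20)
        return amp, build_locus_map([amp], ref)

    def test_single_end_reads_one_row_each(self):
        amp, locus = self._locus()
        reads = [
            make_read("ACGTTCGTTT", 10, name="a"),
            make_read("ATGTTTGTTT", 10, name="b"),
        ]
        mat = build_call_matrix(reads, amp, locus, AssayType.BS)
        assert mat.n_reads == 2
        assert mat.calls.tolist() == [["C", "C"], ["T", "T"]]

    def test_mate_disagreement_consensus_or_n(self):
        amp, locus = self._locus()
        mates = [
            make_read("ACGTTCGTTT", 10, name="frag"),
            make_read("ATGTTCGTTT", 10, name="frag"),  # disagrees at the first CpG
        ]
        mat = build_call_matrix(mates, amp, locus, AssayType.BS)
        assert mat.n_reads == 1
        assert mat.calls[0].tolist() == ["N", "C"]

    def test_mate_agreement_counted_once(self):
        amp, locus = self._locus()
        mates = [make_read("ACGT", 10, name="frag"), make_read("ACGT", 10, name="frag")]
        mat = build_call_matrix(mates, amp, locus, AssayType.BS)
        assert mat.n_reads == 1
        assert mat.calls[0, 0] == "C"

    def test_first_mate_policy_takes_first_informative(self):
        amp, locus = self._locus()
        mates = [make_read("ACGT", 10, name="frag"), make_read("ATGT", 10, name="frag")]
        params = CallingParams(mate_overlap_policy="first_mate")
        mat = build_call_matrix(mates, amp, locus, AssayType.BS, params)
        assert mat.calls[0, 0] == "C"

    def test_all_n_rows_dropped_and_counted(self):
        amp, locus = self._locus()
        reads = [
            make_read("ACGTTCGTTT", 10, name="good"),
            make_read("AAGTTAGTTT", 10, name="bad"),  # A at both CpGs
        ]
        mat = build_call_matrix(reads, amp, locus, AssayType.BS)
        assert mat.n_reads == 1
        assert mat.metadata["n_dropped_all_n"] == 1

    def test_low_mapq_reads_skipped(self):
        amp, locus = self._locus()
        reads = [make_read("ACGTTCGTTT", 10, name="lowmapq", mapq=5)]
        params = CallingParams(min_mapping_quality=30)
        mat = build_call_matrix(reads, amp, locus, AssayType.BS, params)
        assert mat.n_reads == 0
        assert mat.metadata["n_skipped_mapq"] == 1

    def test_chromosome_mismatch_reports_both_names(self):
        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6"}, "SQ": [{"SN": "otherChrom", "LN": 1000}]}
        )
        a = pysam.AlignedSegment(header)
        a.query_name = "r"
        a.query_sequence = "ACGT"
        a.reference_id = 0
        a.reference_start = 10
        a.mapping_quality = 60
        a.cigartuples = [(0, 4)]
        amp, locus = self._locus()
        with pytest.raises(ValueError) as err:
            build_call_matrix([a], amp, locus, AssayType.BS)
        assert "otherChrom" in str(err.value) and "chrT" in str(err.value)

    def test_call_count_conservation(self):
        amp, locus = self._locus()
        reads = [
            make_read("ACGTTCGTTT", 10, name=f"r{k}")
            for k in range(5)
        ] + [make_read("ATGTTAGTTT", 10, name="x")]
        mat = build_call_matrix(reads, amp, locus, AssayType.BS)
        for j in range(mat.n_sites):
            col = mat.column(j)
            assert (col == "C").sum() + (col == "T").sum() + (col == "N").sum() == mat.n_reads

    def test_zero_noise_simulation_reproduces_truth(self, tmp_path, reference, amplicon, locus):
        model = DemethylationModel(
            mode="mixture", u=[0.7] * locus.n_sites, pi=0.5, rho=0.6, leak=0.05,
            depth=150, seed=11, conversion_failure=0.0, seq_error=0.0,
        )
        sam = tmp_path / "sim.sam"
        truth, observed = simulate_alignments(
            model, amplicon, reference, out_sam=str(sam), seed=11
        )
        mat = build_call_matrix(str(sam), amplicon, locus, AssayType.BS)
        assert mat == truth == observed


class TestMatrixTsv:
    def test_round_trip_identity(self, tmp_path):
        mat = make_matrix(["CTN", "CCT"])
        path = tmp_path / "m.tsv"
        write_matrix_tsv(mat, str(path))
        back = read_matrix_tsv(str(path), assay=mat.assay, sites=mat.sites)
        assert back == mat
        assert back.read_ids == mat.read_ids

    def test_unknown_symbol_reports_row_and_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("read_id\t1\t2\nr0\tC\tX\n")
        with pytest.raises(ValueError, match="row 1"):
            read_matrix_tsv(str(path))

    def test_header_only_file_gives_empty_matrix(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("read_id\t1\t2\n")
        mat = read_matrix_tsv(str(path))
        assert mat.n_reads == 0 and mat.n_sites == 2

    def test_truly_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "none.tsv"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_matrix_tsv(str(path))
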