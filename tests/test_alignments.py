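"""Alignment filtering, zone assignment, extraction and FASTQ output."""

import gzip

import pytest

from capcore import (
    AlignmentRecord,
    Zone,
    assign_zone,
    extract_reads,
    filter_alignments,
    read_sam,
    write_fastq,
    write_sam,
)
from capcore.alignments import revcomp


def _rec(read_id="r1", chrom="c1", pos=0, end=None, mapq=60, seq="ACGT", **kw):
    return AlignmentRecord(
        read_id=read_id, chrom=chrom, pos=pos, aln_end=end if end is not None else pos + len(seq),
        mapq=mapq, seq=seq, qual="I" * len(seq), **kw,
    )


class TestFilterAlignments:
    def test_duplicate_flag_predicate(self):
        records = [_rec("dup", is_duplicate=True), _rec("keep")]
        kept, counts = filter_alignments(records, drop_duplicates=True)
        assert [r.read_id for r in kept] == ["keep"]
        assert counts.duplicates == 1

    def test_mapq_threshold_is_strictly_below(self):
        records = [_rec("low", mapq=29), _rec("edge", mapq=30)]
        kept, counts = filter_alignments(records, min_mapq=30)
        assert [r.read_id for r in kept] == ["edge"]
        assert counts.low_mapq == 1

    def test_disabled_predicates_are_identity(self):
        records = [
            _rec("secondary", is_secondary=True),
            _rec("improper", is_paired=True, is_proper_pair=False),
            _rec("dup", is_duplicate=True),
        ]
        kept, counts = filter_alignments(records)
        assert kept == records
        assert counts.kept == counts.raw == 3

    def test_proper_pair_and_secondary_predicates(self):
        records = [
            _rec("proper", is_paired=True, is_proper_pair=True),
            _rec("improper", is_paired=True, is_proper_pair=False),
            _rec("suppl", is_paired=True, is_proper_pair=True, is_supplementary=True),
        ]
        kept, counts = filter_alignments(
            records, require_proper_pair=True, drop_secondary_supplementary=True
        )
        assert [r.read_id for r in kept] == ["proper"]
        assert counts.improper_pair == 1 and counts.secondary_supplementary == 1


class TestAssignZone:
    zones = [Zone("c1", 0, 250), Zone("c1", 255, 400)]

    def test_containment(self):
        assert assign_zone(_rec(pos=100, end=250), self.zones) == "c1_0_250"

    def test_largest_overlap_wins(self):
        # read [240,260): overlap 10 with the first zone, 5 with the second
        assert assign_zone(_rec(pos=240, end=260), self.zones) == "c1_0_250"

    def test_tie_goes_to_leftmost_zone(self):
        zones = [Zone("c1", 0, 100), Zone("c1", 100, 200)]
        assert assign_zone(_rec(pos=95, end=105), zones) == "c1_0_100"

    def test_no_overlap_and_wrong_chromosome(self):
        assert assign_zone(_rec(pos=500, end=600), self.zones) is None
        assert assign_zone(_rec(chrom="c2", pos=10, end=20), self.zones) is None


class TestExtractReads:
    zones = [Zone("c1", 0, 250), Zone("c1", 500, 800)]

    def _pair(self, read_id, pos1, pos2):
        r1 = _rec(read_id, pos=pos1, is_paired=True, is_read1=True)
        r2 = _rec(read_id, pos=pos2, is_paired=True, is_read1=False, is_reverse=True)
        return r1, r2

    def test_both_mates_in_one_zone_stay_paired(self):
        result = extract_reads(list(self._pair("p", 10, 100)), self.zones)
        assert len(result.paired) == 1 and not result.singles
        assert result.per_zone_counts == {"c1_0_250": 2}

    def test_mates_in_two_zones_demoted_to_singles(self):
        result = extract_reads(list(self._pair("s", 100, 600)), self.zones)
        assert not result.paired
        assert sorted(r.read_id for r in result.singles) == ["s", "s"]

    def test_mate_without_zone_makes_survivor_single(self):
        result = extract_reads(list(self._pair("m", 100, 300)), self.zones)
        assert not result.paired
        assert [r.read_id for r in result.singles] == ["m"]
        assert result.dropped == 1

    def test_unpaired_record_in_zone_is_single(self):
        result = extract_reads([_rec("solo", pos=50)], self.zones)
        assert [r.read_id for r in result.singles] == ["solo"]

    def test_more_than_two_records_per_read_rejected(self):
        records = [_rec("x", pos=10), _rec("x", pos=20), _rec("x", pos=30)]
        with pytest.raises(ValueError, match="x"):
            extract_reads(records, self.zones)

    def test_read_conservation_on_simulation(self, capture_sim):
        _cfg, _ref, zones, records, _truth = capture_sim
        result = extract_reads(records, zones)
        assert 2 * len(result.paired) + len(result.singles) + result.dropped == len(records)
        names = {z.name for z in zones}
        for r1, r2 in result.paired:
            assert assign_zone(r1, zones) == assign_zone(r2, zones) in names

    def test_truth_classification_on_simulation(self, capture_sim):
        """Pair/single/dropped classes match the simulator's provenance exactly."""
        _cfg, _ref, zones, records, truth = capture_sim
        result = extract_reads(records, zones)
        paired_ids = {r1.read_id for r1, _ in result.paired}
        single_ids = sorted(r.read_id for r in result.singles)
        expect_paired = {
            rid for rid, zone in truth.origin_zone.items() if zone is not None
        }
        expect_singles = sorted(
            rid for rid in truth.straddle_pairs for _ in range(2)
        )
        assert paired_ids == expect_paired
        assert single_ids == expect_singles
        n_offtarget = sum(1 for z in truth.origin_zone.values() if z is None)
        assert result.dropped == 2 * n_offtarget
        # each straddler's two mates were assigned the two zones it bridges
        for r1, r2 in zip(result.singles[::2], result.singles[1::2]):
            assert (assign_zone(r1, zones), assign_zone(r2, zones)) == truth.straddle_pairs[r1.read_id]


class TestFastqOutput:
    def test_forward_read_written_verbatim(self, tmp_path):
        rec = _rec("f", seq="ACGT")
        from capcore import ExtractionResult

        result = ExtractionResult(singles=[rec])
        _, _, single = write_fastq(
            result, tmp_path / "r1.fq.gz", tmp_path / "r2.fq.gz", tmp_path / "s.fq.gz"
        )
        lines = gzip.open(single, "rt").read().splitlines()
        assert lines == ["@f", "ACGT", "+", "IIII"]

    def test_reverse_read_restored_to_sequencing_orientation(self, tmp_path):
        rec = AlignmentRecord(
            read_id="r", chrom="c1", pos=0, aln_end=4, mapq=60,
            seq="AACC", qual="IJKL", is_reverse=True,
        )
        from capcore import ExtractionResult

        _, _, single = write_fastq(
            ExtractionResult(singles=[rec]),
            tmp_path / "r1.fq.gz", tmp_path / "r2.fq.gz", tmp_path / "s.fq.gz",
        )
        lines = gzip.open(single, "rt").read().splitlines()
        assert lines[1] == "GGTT" == revcomp("AACC")
        assert lines[3] == "LKJI"

    def test_pair_files_stay_synchronized(self, tmp_path, capture_sim):
        _cfg, _ref, zones, records, _truth = capture_sim
        result = extract_reads(records, zones)
        r1, r2, _ = write_fastq(
            result, tmp_path / "r1.fq.gz", tmp_path / "r2.fq.gz", tmp_path / "s.fq.gz"
        )
        ids1 = gzip.open(r1, "rt").read().splitlines()[::4]
        ids2 = gzip.open(r2, "rt").read().splitlines()[::4]
        assert ids1 == ids2 and len(ids1) == len(result.paired)

    def test_empty_result_writes_empty_files(self, tmp_path):
        from capcore import ExtractionResult

        paths = write_fastq(
            ExtractionResult(),
            tmp_path / "r1.fq.gz", tmp_path / "r2.fq.gz", tmp_path / "s.fq.gz",
        )
        for path in paths:
            assert gzip.open(path, "rt").read() == ""


class TestSamRoundTrip:
    def test_flags_and_coordinates_survive(self, tmp_path, capture_sim):
        _cfg, reference, _zones, records, _truth = capture_sim
        path = tmp_path / "aln.sam"
        write_sam(records, reference, path)
        back = read_sam(path)
        assert len(back) == len(records)
        for orig, rt in zip(records, back):
            assert (orig.read_id, orig.chrom, orig.pos, orig.aln_end) == (
                rt.read_id, rt.chrom, rt.pos, rt.aln_end
            )
            assert (orig.is_reverse, orig.is_duplicate, orig.is_proper_pair) == (
                rt.is_reverse, rt.is_duplicate, rt.is_proper_pair
            )
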