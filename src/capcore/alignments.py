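"""Record-level alignment filtering and zone-by-zone read extraction.

After the first mapping round, reads overlapping a zone are pulled out
and converted back to FASTQ for remapping onto the sub-reference.  A
mate pair is only re-emitted as a pair when both mates land in the
*same* zone; a pair whose mates fall in two different zones — or whose
second mate overlaps no zone at all — is demoted to single-end reads so
that the remapper never sees a pair spanning two sub-reference contigs.

The record-level filters mirror the usual pre-extraction clean-up:
duplicate removal, proper-pair requirement, exclusion of secondary and
supplementary alignments, and a mapping-quality floor (reads with MAPQ
strictly below the threshold are dropped).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pysam

from .zones import Zone

__all__ = [
    "AlignmentRecord",
    "ExtractionResult",
    "FilterCounts",
    "filter_alignments",
    "assign_zone",
    "extract_reads",
    "write_fastq",
    "read_sam",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AlignmentRecord:
    """One aligned read with the flags the extraction filters consult."""

    read_id: str
    chrom: str
    pos: int  # 0-based leftmost aligned base
    aln_end: int  # 0-based exclusive end of the aligned reference span
    mapq: int
    seq: str
    qual: str
    is_reverse: bool = False
    is_paired: bool = False
    is_proper_pair: bool = False
    is_read1: bool = True
    is_secondary: bool = False
    is_supplementary: bool = False
    is_duplicate: bool = False
    is_unmapped: bool = False
    mate_chrom: Optional[str] = None
    mate_pos: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"read {self.read_id}: seq/qual length mismatch")
        if not self.is_unmapped and self.aln_end <= self.pos:
            raise ValueError(f"read {self.read_id}: empty aligned span")

    @property
    def is_primary(self) -> bool:
        return not (self.is_secondary or self.is_supplementary)

    def original_seq_qual(self) -> tuple[str, str]:
        """Sequence and quality in sequencing orientation.

        SAM stores reverse-strand alignments reverse-complemented; undo
        that so the emitted FASTQ read matches what the sequencer produced.
        """
        if self.is_reverse:
            return revcomp(self.seq), self.qual[::-1]
        return self.seq, self.qual


@dataclass
class FilterCounts:
    """Per-predicate removal tally feeding the nb_reads_per_sample report."""

    raw: int = 0
    duplicates: int = 0
    improper_pair: int = 0
    secondary_supplementary: int = 0
    low_mapq: int = 0
    unmapped: int = 0
    kept: int = 0


@dataclass
class ExtractionResult:
    paired: list[tuple[AlignmentRecord, AlignmentRecord]] = field(default_factory=list)
    singles: list[AlignmentRecord] = field(default_factory=list)
    dropped: int = 0
    per_zone_counts: dict[str, int] = field(default_factory=dict)


def filter_alignments(
    records: Sequence[AlignmentRecord],
    drop_duplicates: bool = False,
    require_proper_pair: bool = False,
    drop_secondary_supplementary: bool = False,
    min_mapq: Optional[int] = None,
) -> tuple[list[AlignmentRecord], FilterCounts]:
    """Apply the enabled record-level predicates; unmapped reads never pass.

    With every predicate disabled this is the identity on mapped records.
    """
    counts = FilterCounts(raw=len(records))
    kept = []
    for rec in records:
        if rec.is_unmapped:
            counts.unmapped += 1
            continue
        if drop_duplicates and rec.is_duplicate:
            counts.duplicates += 1
            continue
        if require_proper_pair and not rec.is_proper_pair:
            counts.improper_pair += 1
            continue
        if drop_secondary_supplementary and not rec.is_primary:
            counts.secondary_supplementary += 1
            continue
        if min_mapq is not None and rec.mapq < min_mapq:
            counts.low_mapq += 1
            continue
        kept.append(rec)
    counts.kept = len(kept)
    return kept, counts


def assign_zone(record: AlignmentRecord, zones: Sequence[Zone]) -> Optional[str]:
    """Assign a record to the zone it overlaps most.

    Any overlap qualifies; ties go to the leftmost zone; ``None`` when
    the aligned span touches no zone.
    """
    best: Optional[str] = None
    best_overlap = 0
    for zone in zones:
        if zone.chrom != record.chrom:
            continue
        overlap = min(record.aln_end, zone.end) - max(record.pos, zone.start)
        if overlap > best_overlap:
            best_overlap = overlap
            best = zone.name
    return best


def extract_reads(
    records: Sequence[AlignmentRecord], zones: Sequence[Zone]
) -> ExtractionResult:
    """Zone-by-zone extraction with single-end demotion.

    Both mates in one zone -> the pair survives as a pair.  Mates in two
    different zones -> both demoted to singles.  Mate in no zone (or no
    mate present) -> the in-zone record becomes a single; the zoneless
    record counts as dropped.
    """
    by_read: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        by_read.setdefault(rec.read_id, []).append(rec)

    result = ExtractionResult()

    def _count(rec: AlignmentRecord, zone_name: str) -> None:
        result.per_zone_counts[zone_name] = result.per_zone_counts.get(zone_name, 0) + 1

    for read_id, group in by_read.items():
        if len(group) > 2:
            raise ValueError(
                f"read {read_id}: {len(group)} primary records; "
                "remove secondary/supplementary alignments first"
            )
        assignments = [assign_zone(rec, zones) for rec in group]
        if len(group) == 2 and assignments[0] is not None and assignments[0] == assignments[1]:
            r1, r2 = sorted(group, key=lambda r: not r.is_read1)
            result.paired.append((r1, r2))
            _count(r1, assignments[0])
            _count(r2, assignments[0])
            continue
        for rec, zone_name in zip(group, assignments):
            if zone_name is None:
                result.dropped += 1
            else:
                result.singles.append(rec)
                _count(rec, zone_name)
    return result


def write_fastq(
    result: ExtractionResult,
    out_paired_r1,
    out_paired_r2,
    out_single,
) -> tuple[str, str, str]:
    """Write extracted reads as gzip FASTQ, restoring sequencing orientation.

    R1/R2 files stay synchronized (same order, same ids).
    """

    def _record(fh, rec: AlignmentRecord) -> None:
        seq, qual = rec.original_seq_qual()
        fh.write(f"@{rec.read_id}\n{seq}\n+\n{qual}\n")

    with gzip.open(out_paired_r1, "wt") as r1, gzip.open(out_paired_r2, "wt") as r2:
        for rec1, rec2 in result.paired:
            _record(r1, rec1)
            _record(r2, rec2)
    with gzip.open(out_single, "wt") as single:
        for rec in result.singles:
            _record(single, rec)
    return str(out_paired_r1), str(out_paired_r2), str(out_single)


def read_sam(path) -> list[AlignmentRecord]:
    """Load SAM-format text into alignment records (via pysam)."""
    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            seq = aln.query_sequence or ""
            if aln.query_qualities is not None:
                qual = "".join(chr(q + 33) for q in aln.query_qualities)
            else:
                qual = "I" * len(seq)
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    chrom=aln.reference_name,
                    pos=aln.reference_start,
                    aln_end=aln.reference_end,
                    mapq=aln.mapping_quality,
                    seq=seq,
                    qual=qual,
                    is_reverse=aln.is_reverse,
                    is_paired=aln.is_paired,
                    is_proper_pair=aln.is_proper_pair,
                    is_read1=not aln.is_read2,
                    is_secondary=aln.is_secondary,
                    is_supplementary=aln.is_supplementary,
                    is_duplicate=aln.is_duplicate,
                    is_unmapped=aln.is_unmapped,
                    mate_chrom=aln.next_reference_name if aln.is_paired else None,
                    mate_pos=aln.next_reference_start if aln.is_paired else None,
                )
            )
    return records
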