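"""Coverage-driven zone calling and sub-reference construction.

A *zone* is a contiguous interval of the full reference that is either
targeted by capture baits (user-supplied BED) or empirically covered by
reads (coverage-driven calling).  Each zone becomes one contig of the
*sub-reference*, the reduced FASTA used for the second ("targeted")
mapping round.  Coordinates are BED-style 0-based half-open throughout;
1-based coordinates appear only at the VCF boundary (see
:mod:`capcore.liftover`).

Coverage-driven calling follows a three-parameter rule:

1. mark every base whose mean per-sample depth is >= ``min_mean_cov``;
2. merge consecutive marked runs separated by a gap *strictly* smaller
   than ``min_dist`` (the gap bases are retained, so a merged zone is a
   single contiguous interval);
3. discard merged regions shorter than ``min_length``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Zone",
    "ZoneConfig",
    "DepthProfile",
    "mean_depth_profile",
    "call_zones",
    "merge_intervals",
    "extract_subreference",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
]

_ZONE_NAME_RE = re.compile(r"^(?P<chrom>.+)_(?P<start>\d+)_(?P<end>\d+)$")


@dataclass(frozen=True, order=True)
class Zone:
    """One sub-reference contig: an interval on the full reference.

    ``name`` encodes the full-reference coordinates as
    ``{chrom}_{start}_{end}`` (0-based half-open) so that sub-reference
    contig names can be parsed back into intervals during lift-over.
    """

    chrom: str
    start: int
    end: int
    name: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid zone interval {self.chrom}:{self.start}-{self.end}"
            )
        if not self.name:
            object.__setattr__(self, "name", f"{self.chrom}_{self.start}_{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    @classmethod
    def from_name(cls, name: str) -> "Zone":
        """Parse a ``{chrom}_{start}_{end}`` contig name back to a zone."""
        m = _ZONE_NAME_RE.match(name)
        if m is None:
            raise ValueError(f"contig name {name!r} does not encode a zone")
        return cls(m["chrom"], int(m["start"]), int(m["end"]), name)


@dataclass(frozen=True)
class ZoneConfig:
    """Parameters of coverage-driven zone calling.

    min_mean_cov
        minimum mean depth per sample for a base to be marked (reads);
        inclusive, so the durum-wheat setting of 1 keeps bases averaging
        exactly one read per sample.
    min_dist
        marked runs closer than this many bp are merged (strict:
        a gap equal to ``min_dist`` does not merge).
    min_length
        merged regions shorter than this many bp are discarded.
    """

    min_mean_cov: float = 1.0
    min_dist: int = 100
    min_length: int = 100

    def __post_init__(self) -> None:
        if not np.isfinite(self.min_mean_cov) or self.min_mean_cov < 0:
            raise ValueError("min_mean_cov must be finite and >= 0")
        if self.min_dist < 0:
            raise ValueError("min_dist must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass
class DepthProfile:
    """Mean per-sample depth at every base of one chromosome."""

    chrom: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1:
            raise ValueError("depth must be one-dimensional")
        if np.any(self.depth < 0):
            raise ValueError("depths must be non-negative")

    def __len__(self) -> int:
        return self.depth.shape[0]


def mean_depth_profile(
    per_sample_depths: Mapping[str, Sequence[int]], chrom: str = "chr"
) -> DepthProfile:
    """Average per-base depth over samples.

    The denominator is the total number of samples, including samples
    with zero coverage at the base.
    """
    if not per_sample_depths:
        raise ValueError("at least one sample is required")
    arrays = [np.asarray(d, dtype=float) for d in per_sample_depths.values()]
    lengths = {a.shape[0] for a in arrays}
    if len(lengths) != 1:
        raise ValueError(f"samples disagree on chromosome length: {sorted(lengths)}")
    return DepthProfile(chrom, np.mean(arrays, axis=0))


def call_zones(profile: DepthProfile, cfg: ZoneConfig) -> list[Zone]:
    """Call zones on one chromosome from its mean-depth profile.

    Returns sorted, pairwise-disjoint zones in 0-based half-open
    coordinates; an empty list when no base passes the threshold or no
    merged region reaches ``min_length``.
    """
    marked = profile.depth >= cfg.min_mean_cov
    if not marked.any():
        return []
    # run boundaries of the marked mask
    diff = np.diff(marked.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1) + 1
    if marked[0]:
        starts = np.concatenate(([0], starts))
    if marked[-1]:
        ends = np.concatenate((ends, [marked.shape[0]]))

    merged: list[list[int]] = []
    for s, e in zip(starts.tolist(), ends.tolist()):
        if merged and s - merged[-1][1] < cfg.min_dist:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [
        Zone(profile.chrom, s, e)
        for s, e in merged
        if e - s >= cfg.min_length
    ]


def merge_intervals(intervals: Iterable[tuple[str, int, int]]) -> list[Zone]:
    """Merge overlapping or touching intervals into sorted disjoint zones.

    Touching half-open intervals (gap 0) merge: at base resolution they
    are indistinguishable from overlapping ones.
    """
    checked = []
    for i, (chrom, start, end) in enumerate(intervals):
        if start < 0 or end <= start:
            raise ValueError(
                f"invalid interval on line {i + 1}: {chrom}\t{start}\t{end}"
            )
        checked.append((chrom, int(start), int(end)))
    checked.sort()
    merged: list[list] = []
    for chrom, start, end in checked:
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], end)
        else:
            merged.append([chrom, start, end])
    return [Zone(c, s, e) for c, s, e in merged]


def extract_subreference(
    reference: Mapping[str, str], zones: Sequence[Zone]
) -> list[tuple[str, str]]:
    """Slice zone sequences out of the full reference.

    Returns ``(zone.name, sequence)`` pairs in zone order; the
    concatenated length equals the summed zone lengths.
    """
    records = []
    for zone in zones:
        if zone.chrom not in reference:
            raise KeyError(f"zone {zone.name}: chromosome {zone.chrom!r} not in reference")
        seq = reference[zone.chrom]
        if zone.end > len(seq):
            raise ValueError(
                f"zone {zone.name} extends past end of {zone.chrom} ({len(seq)} bp)"
            )
        records.append((zone.name, str(seq[zone.start : zone.end])))
    return records


# ---------------------------------------------------------------------------
# file I/O

def read_bed(path) -> list[Zone]:
    """Read zones from a 3+ column BED file (column 4, when present, is the name)."""
    zones = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{ln}: expected >= 3 BED columns")
            name = cols[3] if len(cols) > 3 else ""
            zones.append(Zone(cols[0], int(cols[1]), int(cols[2]), name))
    return zones


def write_bed(zones: Sequence[Zone], path) -> None:
    with open(path, "w") as fh:
        for z in zones:
            fh.write(f"{z.chrom}\t{z.start}\t{z.end}\t{z.name}\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    """Write FASTA wrapped at 60 columns."""
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")
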