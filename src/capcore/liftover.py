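"""Lift variant coordinates from sub-reference contigs back to the full reference.

Each sub-reference contig is one zone whose name encodes its
full-reference interval (``{chrom}_{start}_{end}``, 0-based half-open).
Lifting a 1-based position ``sub_pos`` on such a contig is a pure
offset: ``full_pos = zone.start + sub_pos``.

``lift_vcf`` rewrites CHROM and POS (and the ``##contig`` header lines)
at the text level so every other field of every record is preserved
byte-for-byte; records are re-sorted by full-reference coordinates so
the output is ready for indexing.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .zones import Zone

__all__ = ["ZoneIndex", "lift_position", "lift_vcf"]


@dataclass
class ZoneIndex:
    """Zone lookup by sub-contig name, plus full-reference chromosome sizes."""

    by_name: dict[str, Zone]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_zones(
        cls, zones: Sequence[Zone], chrom_lengths: Mapping[str, int] | None = None
    ) -> "ZoneIndex":
        by_name: dict[str, Zone] = {}
        for z in zones:
            if z.name in by_name:
                raise ValueError(f"duplicate zone name {z.name}")
            by_name[z.name] = z
        lengths = dict(chrom_lengths or {})
        for z in zones:
            if z.chrom in lengths and z.end > lengths[z.chrom]:
                raise ValueError(
                    f"zone {z.name} extends past {z.chrom} length {lengths[z.chrom]}"
                )
        return cls(by_name, lengths)

    def lookup(self, sub_contig: str) -> Zone:
        zone = self.by_name.get(sub_contig)
        if zone is None:
            # tolerate contigs named per convention but absent from the BED
            try:
                zone = Zone.from_name(sub_contig)
            except ValueError:
                raise KeyError(f"unknown sub-reference contig {sub_contig!r}") from None
            if self.by_name:
                raise KeyError(f"contig {sub_contig!r} not in the zone index")
        return zone


def lift_position(sub_contig: str, sub_pos: int, index: ZoneIndex) -> tuple[str, int]:
    """Map a 1-based sub-reference position to (chrom, 1-based full position)."""
    zone = index.lookup(sub_contig)
    if not 1 <= sub_pos <= len(zone):
        raise ValueError(
            f"position {sub_pos} outside contig {sub_contig} (length {len(zone)})"
        )
    return zone.chrom, zone.start + sub_pos


def _open_text(path):
    path = str(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path)


def lift_vcf(in_vcf, out_vcf, index: ZoneIndex) -> int:
    """Rewrite a sub-reference VCF onto full-reference coordinates.

    Header ``##contig`` lines are replaced by the full-reference
    chromosomes (with lengths when the index knows them); records are
    re-sorted by (chrom, pos).  Returns the number of records written.

    All record fields other than CHROM/POS are copied verbatim.
    """
    header_out: list[str] = []
    records: list[tuple[str, int, str]] = []
    contigs_written = False
    chrom_order = {c: i for i, c in enumerate(index.chrom_lengths)}

    def _contig_lines() -> list[str]:
        chroms = dict(index.chrom_lengths)
        if not chroms:
            seen: dict[str, int] = {}
            for z in index.by_name.values():
                seen[z.chrom] = max(seen.get(z.chrom, 0), z.end)
            chroms = seen
        return [f"##contig=<ID={c},length={l}>" for c, l in chroms.items()]

    with _open_text(in_vcf) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##contig"):
                if not contigs_written:
                    header_out.extend(_contig_lines())
                    contigs_written = True
                continue
            if line.startswith("#"):
                if line.startswith("#CHROM") and not contigs_written:
                    header_out.extend(_contig_lines())
                    contigs_written = True
                header_out.append(line)
                continue
            fields = line.split("\t", 2)
            if len(fields) < 3:
                raise ValueError(f"malformed VCF record: {line!r}")
            try:
                chrom, pos = lift_position(fields[0], int(fields[1]), index)
            except KeyError as exc:
                raise ValueError(f"cannot lift record {fields[0]}:{fields[1]}: {exc}")
            if chrom in index.chrom_lengths and pos > index.chrom_lengths[chrom]:
                raise ValueError(
                    f"lifted position {chrom}:{pos} exceeds chromosome length"
                )
            records.append((chrom, pos, fields[2]))

    records.sort(key=lambda r: (chrom_order.get(r[0], len(chrom_order)), r[0], r[1]))
    with open(out_vcf, "w") as out:
        for line in header_out:
            out.write(line + "\n")
        for chrom, pos, rest in records:
            out.write(f"{chrom}\t{pos}\t{rest}\n")
    return len(records)
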