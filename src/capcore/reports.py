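"""Tabular run reports and the append-only provenance log."""

from __future__ import annotations

import datetime
from typing import Mapping, Sequence

import pandas as pd

from .alignments import FilterCounts

__all__ = [
    "nb_reads_per_sample_table",
    "write_nb_reads_per_sample",
    "append_provenance",
]


def nb_reads_per_sample_table(
    counts: Mapping[str, FilterCounts],
    extracted: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-sample read counts across the filtering stages.

    One row per sample: raw count, removals per predicate, reads kept,
    and (when available) reads extracted into zones.  Samples with zero
    reads still get a row of zeros.
    """
    rows = []
    for sample, c in counts.items():
        row = {
            "sample": sample,
            "raw": c.raw,
            "unmapped": c.unmapped,
            "duplicates_removed": c.duplicates,
            "improper_pair_removed": c.improper_pair,
            "secondary_supplementary_removed": c.secondary_supplementary,
            "low_mapq_removed": c.low_mapq,
            "kept": c.kept,
        }
        if extracted is not None:
            row["extracted"] = extracted.get(sample, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def write_nb_reads_per_sample(counts, path, extracted=None) -> None:
    nb_reads_per_sample_table(counts, extracted).to_csv(path, sep="\t", index=False)


def append_provenance(
    path,
    command: str,
    config: Mapping,
    inputs: Sequence[str] = (),
    outputs: Sequence[str] = (),
    version: str | None = None,
) -> None:
    """Append one human-readable run block; never truncates earlier runs."""
    if version is None:
        from . import __version__ as version
    stamp = datetime.datetime.now().isoformat(timespec="seconds")
    with open(path, "a") as fh:
        fh.write(f"==== run {stamp} ====\n")
        fh.write(f"tool: capcore {version}\n")
        fh.write(f"command: {command}\n")
        fh.write("config:\n")
        for key, value in config.items():
            fh.write(f"  {key}: {value}\n")
        if inputs:
            fh.write("inputs:\n")
            for f in inputs:
                fh.write(f"  {f}\n")
        if outputs:
            fh.write("outputs:\n")
            for f in outputs:
                fh.write(f"  {f}\n")
        fh.write("\n")
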