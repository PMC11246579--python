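"""Synthetic capture-genotyping data with known truth.

Everything the toolkit consumes can be generated here with no external
data: a random reference with sparsely placed target zones, capture-like
paired alignments (configurable PCR-duplicate and off-target rates, plus
pairs deliberately straddling two zones to exercise single-end
demotion), and multi-population genotype matrices whose inbreeding
coefficient, divergence and planted filter violations are known exactly.

The defaults emulate a desk-scale version of a selfing-cereal capture
experiment: zones covering a small fraction of the genome, a high PCR
duplicate rate (capture of a huge genome yields mostly duplicates),
selfing-equilibrium inbreeding (F ~ 0.92 at ~4% outcrossing), and
population divergence generated under the Balding–Nichols model so the
true Fst is a tunable parameter.

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .alignments import AlignmentRecord, revcomp
from .filtering import GenotypeCall, VariantSite
from .zones import Zone

__all__ = [
    "SimulationConfig",
    "AlignmentTruth",
    "GenotypeTruth",
    "simulate_reference",
    "simulate_alignments",
    "simulate_genotypes",
    "write_sam",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the reference conditions.

    Capture/alignment side: ``duplicate_rate`` 0.8 reflects the very
    high PCR duplication seen when capturing a small target in a huge
    genome; ``off_target_rate`` 0.1 is a realistic hybridization leak.
    Genotype side: ``inbreeding_f`` 0.92 is the selfing-equilibrium
    value at 4% outcrossing; ``target_fst`` 0.1 a moderate divergence.
    """

    seed: int = 0
    # reference / zones
    n_chrom: int = 2
    chrom_length: int = 100_000
    n_zones: int = 20
    zone_length: int = 300
    min_zone_gap: int = 250  # >= 2 x the default merge distance
    # alignments
    n_samples: int = 4
    n_pairs_per_sample: int = 500
    read_length: int = 100
    insert_size: int = 250
    duplicate_rate: float = 0.8
    off_target_rate: float = 0.1
    n_straddle_pairs: int = 5
    base_mapq: int = 60
    # genotypes
    populations: Sequence[tuple[str, int]] = (("DD", 20), ("DC", 20))
    target_fst: float = 0.1
    inbreeding_f: float = 0.92
    n_sites: int = 500
    ancestral_maf_range: tuple[float, float] = (0.1, 0.5)
    depth_model: float = 20.0  # mean reads per genotype (Poisson)
    gq_slope: float = 4.0  # GQ grows roughly linearly with DP
    gq_noise: float = 3.0
    # planted filter violations (counts of extra sites appended)
    n_low_qual_sites: int = 0
    n_excess_het_sites: int = 0
    n_no_minor_hom_sites: int = 0

    def __post_init__(self) -> None:
        for frac in (self.duplicate_rate, self.off_target_rate, self.target_fst,
                     self.inbreeding_f):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("rates and coefficients must lie in [0, 1]")


@dataclass
class AlignmentTruth:
    """Per-read provenance of a simulated alignment set."""

    origin_zone: dict[str, Optional[str]] = field(default_factory=dict)
    straddle_pairs: dict[str, tuple[str, str]] = field(default_factory=dict)
    n_duplicates: int = 0
    n_reads: int = 0


@dataclass
class GenotypeTruth:
    """Ground truth behind a simulated genotype matrix."""

    inbreeding_f: float
    target_fst: float
    pop_freqs: dict[str, np.ndarray]  # population -> per-site ALT frequency
    low_qual_pos: list[int] = field(default_factory=list)
    excess_het_pos: list[int] = field(default_factory=list)
    no_minor_hom_pos: list[int] = field(default_factory=list)


def simulate_reference(
    cfg: SimulationConfig,
) -> tuple[dict[str, str], list[Zone]]:
    """Random reference plus disjoint zones spaced at least ``min_zone_gap`` apart."""
    rng = np.random.default_rng(cfg.seed)
    bases = np.array(list("ACGT"))
    reference = {
        f"chr{i + 1}": "".join(rng.choice(bases, size=cfg.chrom_length))
        for i in range(cfg.n_chrom)
    }
    stride = cfg.zone_length + cfg.min_zone_gap
    per_chrom = (cfg.chrom_length - cfg.min_zone_gap) // stride
    if per_chrom * cfg.n_chrom < cfg.n_zones:
        raise ValueError(
            f"cannot place {cfg.n_zones} zones of {cfg.zone_length} bp "
            f"with gaps >= {cfg.min_zone_gap} bp"
        )
    zones: list[Zone] = []
    slots = [(c, k) for c in reference for k in range(per_chrom)]
    chosen = sorted(
        rng.choice(len(slots), size=cfg.n_zones, replace=False).tolist()
    )
    for slot in chosen:
        chrom, k = slots[slot]
        # jitter within the slot keeps the layout irregular but disjoint
        jitter = int(rng.integers(0, cfg.min_zone_gap // 2 + 1))
        start = cfg.min_zone_gap // 2 + k * stride + jitter
        zones.append(Zone(chrom, start, start + cfg.zone_length))
    zones.sort()
    return reference, zones


def _read_pair(
    rng, cfg: SimulationConfig, reference, chrom: str, frag_start: int, read_id: str,
    mapq: int, proper: bool, duplicate: bool,
) -> tuple[AlignmentRecord, AlignmentRecord]:
    seq = reference[chrom]
    rl = cfg.read_length
    r1_start = frag_start
    r2_start = frag_start + cfg.insert_size - rl
    qual = "I" * rl
    common = dict(
        read_id=read_id, chrom=chrom, mapq=mapq, qual=qual,
        is_paired=True, is_proper_pair=proper, is_duplicate=duplicate,
    )
    rec1 = AlignmentRecord(
        pos=r1_start, aln_end=r1_start + rl, seq=seq[r1_start : r1_start + rl],
        is_reverse=False, is_read1=True,
        mate_chrom=chrom, mate_pos=r2_start, **common,
    )
    rec2 = AlignmentRecord(
        pos=r2_start, aln_end=r2_start + rl, seq=seq[r2_start : r2_start + rl],
        is_reverse=True, is_read1=False,
        mate_chrom=chrom, mate_pos=r1_start, **common,
    )
    return rec1, rec2


def simulate_alignments(
    cfg: SimulationConfig,
    reference: dict[str, str],
    zones: Sequence[Zone],
) -> tuple[list[AlignmentRecord], AlignmentTruth]:
    """Capture-like paired alignments with duplicates, off-target reads and straddlers.

    Each fragment is on-target (drawn inside one zone) with probability
    ``1 - off_target_rate`` and uniform background otherwise; each is
    independently flagged as a PCR duplicate (an exact copy of an
    earlier same-locus fragment when one exists) with probability
    ``duplicate_rate``.  ``n_straddle_pairs`` extra properly-paired
    fragments bridge two consecutive zones of one chromosome.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    truth = AlignmentTruth()
    records: list[AlignmentRecord] = []
    zones = sorted(zones)
    by_chrom: dict[str, list[Zone]] = {}
    for z in zones:
        by_chrom.setdefault(z.chrom, []).append(z)

    def overlaps_zone(chrom: str, start: int, end: int) -> Optional[str]:
        for z in by_chrom.get(chrom, []):
            if min(end, z.end) - max(start, z.start) > 0:
                return z.name
        return None

    seen_fragments: dict[str, list[tuple[str, int]]] = {}
    n = 0
    for sample_i in range(cfg.n_samples):
        for _ in range(cfg.n_pairs_per_sample):
            n += 1
            read_id = f"S{sample_i}_read{n}"
            duplicate = bool(rng.random() < cfg.duplicate_rate)
            on_target = rng.random() >= cfg.off_target_rate
            if on_target:
                zone = zones[int(rng.integers(0, len(zones)))]
                lo = zone.start
                hi = max(lo + 1, zone.end - cfg.insert_size)
                key = zone.name
            else:
                zone = None
                key = "offtarget"
            if duplicate and seen_fragments.get(key):
                chrom, frag_start = seen_fragments[key][
                    int(rng.integers(0, len(seen_fragments[key])))
                ]
            elif on_target:
                chrom = zone.chrom
                frag_start = int(rng.integers(lo, hi))
            else:
                # resample until the whole fragment is zone-free so truth is exact
                while True:
                    chrom = f"chr{int(rng.integers(1, cfg.n_chrom + 1))}"
                    frag_start = int(
                        rng.integers(0, cfg.chrom_length - cfg.insert_size)
                    )
                    if overlaps_zone(chrom, frag_start, frag_start + cfg.insert_size) is None:
                        break
            if not duplicate:
                seen_fragments.setdefault(key, []).append((chrom, frag_start))
            rec1, rec2 = _read_pair(
                rng, cfg, reference, chrom, frag_start, read_id,
                mapq=cfg.base_mapq, proper=True, duplicate=duplicate,
            )
            records.extend((rec1, rec2))
            origin = overlaps_zone(chrom, rec1.pos, rec2.aln_end) if on_target else None
            truth.origin_zone[read_id] = origin
            if duplicate:
                truth.n_duplicates += 2

    # straddling pairs: R1 overlaps one zone, R2 the next zone on the chromosome
    placed = 0
    for chrom, chrom_zones in by_chrom.items():
        for za, zb in zip(chrom_zones, chrom_zones[1:]):
            if placed >= cfg.n_straddle_pairs:
                break
            n += 1
            read_id = f"straddle{placed}"
            rl = cfg.read_length
            r1_start = max(za.start, za.end - rl // 2)  # half in, half out
            r2_start = max(zb.start, zb.start - rl // 2)
            seq = reference[chrom]
            qual = "I" * rl
            rec1 = AlignmentRecord(
                read_id=read_id, chrom=chrom, pos=r1_start, aln_end=r1_start + rl,
                mapq=cfg.base_mapq, seq=seq[r1_start : r1_start + rl], qual=qual,
                is_paired=True, is_proper_pair=True, is_read1=True,
                mate_chrom=chrom, mate_pos=r2_start,
            )
            rec2 = AlignmentRecord(
                read_id=read_id, chrom=chrom, pos=r2_start, aln_end=r2_start + rl,
                mapq=cfg.base_mapq, seq=seq[r2_start : r2_start + rl], qual=qual,
                is_reverse=True, is_paired=True, is_proper_pair=True, is_read1=False,
                mate_chrom=chrom, mate_pos=r1_start,
            )
            records.extend((rec1, rec2))
            truth.straddle_pairs[read_id] = (za.name, zb.name)
            placed += 1
        if placed >= cfg.n_straddle_pairs:
            break

    truth.n_reads = len(records)
    return records, truth


def _balding_nichols(rng, ancestral: np.ndarray, fst: float) -> np.ndarray:
    if fst == 0.0:
        return ancestral.copy()
    shape = (1.0 - fst) / fst
    return rng.beta(ancestral * shape, (1.0 - ancestral) * shape)


def _draw_genotypes(rng, freqs: np.ndarray, n_ind: int, f: float) -> np.ndarray:
    """Dosage matrix (sites x individuals) under inbreeding coefficient f."""
    p = freqs[:, None]
    hom_alt = p * p + f * p * (1 - p)
    het = 2 * p * (1 - p) * (1 - f)
    u = rng.random((freqs.size, n_ind))
    return np.where(u < hom_alt, 2, np.where(u < hom_alt + het, 1, 0)).astype(int)


def simulate_genotypes(
    cfg: SimulationConfig,
) -> tuple[list[VariantSite], list[str], dict[str, str], GenotypeTruth]:
    """Multi-population genotype matrix as VariantSites, with exact truth.

    Per site the ancestral ALT frequency is uniform in
    ``ancestral_maf_range``; each population's frequency is drawn from
    the Balding–Nichols beta at ``target_fst``; genotypes follow the
    inbreeding model (hom/het probabilities tilted by ``inbreeding_f``).
    DP is Poisson around ``depth_model`` and GQ increases with DP.
    Appended after the regular sites, in order: low-QUAL sites,
    excess-heterozygosity sites (FIS << 0), and sites lacking a minor
    homozygote — each recorded in the returned truth.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    pops = list(cfg.populations)
    samples = [f"{label}_{i:03d}" for label, n_ind in pops for i in range(n_ind)]
    pop_of = {}
    for label, n_ind in pops:
        for i in range(n_ind):
            pop_of[f"{label}_{i:03d}"] = label

    n_regular = cfg.n_sites
    lo, hi = cfg.ancestral_maf_range
    ancestral = rng.uniform(lo, hi, size=n_regular)
    truth = GenotypeTruth(
        inbreeding_f=cfg.inbreeding_f, target_fst=cfg.target_fst, pop_freqs={}
    )
    dosage_blocks = []
    for label, n_ind in pops:
        freqs = _balding_nichols(rng, ancestral, cfg.target_fst)
        truth.pop_freqs[label] = freqs
        dosage_blocks.append(_draw_genotypes(rng, freqs, n_ind, cfg.inbreeding_f))
    dosages = np.concatenate(dosage_blocks, axis=1)  # sites x samples

    sites: list[VariantSite] = []
    pos = 0
    bases = "ACGT"

    def _qual(low: bool) -> float:
        return float(rng.uniform(5, 29)) if low else float(rng.uniform(60, 900))

    def _site(dosage_row: np.ndarray, qual: float) -> VariantSite:
        nonlocal pos
        pos += 100
        ref = bases[int(rng.integers(0, 4))]
        alt = rng.choice([b for b in bases if b != ref])
        calls = {}
        for j, sample in enumerate(samples):
            dp = int(rng.poisson(cfg.depth_model))
            gq = int(np.clip(cfg.gq_slope * dp + rng.normal(0, cfg.gq_noise), 0, 99))
            d = int(dosage_row[j])
            alleles = (d > 0 and 1 or 0, d > 1 and 1 or 0)
            alleles = tuple(sorted(alleles))
            calls[sample] = GenotypeCall(alleles=alleles, dp=dp, gq=gq)
        return VariantSite(
            chrom="chr1", pos=pos, ref=ref, alts=[str(alt)], qual=qual, calls=calls
        )

    for i in range(n_regular):
        sites.append(_site(dosages[i], _qual(low=False)))

    for _ in range(cfg.n_low_qual_sites):
        row = _draw_genotypes(rng, np.array([0.3]), len(samples), cfg.inbreeding_f)[0]
        sites.append(_site(row, _qual(low=True)))
        truth.low_qual_pos.append(sites[-1].pos)

    for _ in range(cfg.n_excess_het_sites):
        # every individual heterozygous: FIS = -1 (collapsed-paralog signature)
        row = np.ones(len(samples), dtype=int)
        sites.append(_site(row, _qual(low=False)))
        truth.excess_het_pos.append(sites[-1].pos)

    for _ in range(cfg.n_no_minor_hom_sites):
        # minor allele seen only in a couple of heterozygotes
        row = np.zeros(len(samples), dtype=int)
        row[:2] = 1
        sites.append(_site(row, _qual(low=False)))
        truth.no_minor_hom_pos.append(sites[-1].pos)

    return sites, samples, pop_of, truth


def write_sam(
    records: Sequence[AlignmentRecord], reference: dict[str, str], path
) -> None:
    """Write alignment records as SAM text (via pysam)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in reference.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        refs = {c: i for i, c in enumerate(reference)}
        for rec in records:
            a = pysam.AlignedSegment()
            a.query_name = rec.read_id
            a.query_sequence = rec.seq
            a.query_qualities = pysam.qualitystring_to_array(rec.qual)
            a.reference_id = refs[rec.chrom]
            a.reference_start = rec.pos
            a.mapping_quality = rec.mapq
            a.cigarstring = f"{len(rec.seq)}M"
            flag = 0
            if rec.is_paired:
                flag |= 0x1
                flag |= 0x40 if rec.is_read1 else 0x80
                if rec.is_proper_pair:
                    flag |= 0x2
                if rec.mate_chrom is not None:
                    a.next_reference_id = refs[rec.mate_chrom]
                    a.next_reference_start = rec.mate_pos
            if rec.is_reverse:
                flag |= 0x10
            if rec.is_secondary:
                flag |= 0x100
            if rec.is_duplicate:
                flag |= 0x400
            if rec.is_supplementary:
                flag |= 0x800
            a.flag = flag
            out.write(a)
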