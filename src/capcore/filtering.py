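"""Four-stage VCF filtering cascade with population-genetic criteria.

The cascade mirrors the usual order of operations when cleaning a raw
multi-sample callset:

* step 01 — *genotype masking*: individual calls supported by too few
  reads (DP < ``min_dp``) or with low genotype confidence
  (GQ <= ``min_gq``) are set to missing; the site itself survives.
* step 02 — *locus filtering*: sites with QUAL below ``min_qual`` or
  with a missing-call fraction above ``max_f_missing`` are dropped.
* step 03 — *sample filtering*: samples whose missing fraction over the
  surviving sites exceeds ``max_sample_missing`` are removed everywhere.
* step 04 — *population-genetic filtering*: restrict to biallelic sites
  (evaluated on the alleles actually observed after masking), then drop
  sites whose FIS falls below ``min_fis`` — in a predominantly selfing
  species, excess heterozygosity (low FIS) marks collapsed paralogs —
  and sites where the minor allele is never observed homozygous.

After each step the number of surviving SNPs and their Ts/Tv ratio are
recorded; a rising Ts/Tv along the cascade is the classic sign that the
filters remove artefactual calls faster than genuine ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .popgen import TsTvUndefined, site_stats_from_array, tstv_ratio

__all__ = [
    "GenotypeCall",
    "VariantSite",
    "FilterConfig",
    "FilterStepReport",
    "mask_genotypes",
    "filter_loci",
    "filter_samples",
    "popgen_filter",
    "run_cascade",
    "read_vcf",
    "write_vcf",
    "write_step_reports",
]

MISSING = None


@dataclass(frozen=True)
class GenotypeCall:
    """One diploid call: allele indices (None = missing), read depth, genotype quality."""

    alleles: Optional[tuple[int, int]]
    dp: Optional[int] = None
    gq: Optional[int] = None

    @property
    def is_missing(self) -> bool:
        return self.alleles is None


@dataclass
class VariantSite:
    """One VCF row with per-sample calls."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: list[str]
    qual: float
    calls: dict[str, GenotypeCall]
    id: str = "."

    def observed_alleles(self) -> set[int]:
        out: set[int] = set()
        for call in self.calls.values():
            if call.alleles is not None:
                out.update(call.alleles)
        return out

    def missing_fraction(self) -> float:
        if not self.calls:
            return 1.0
        return sum(c.is_missing for c in self.calls.values()) / len(self.calls)

    def dosages(self, alt_index: int = 1) -> np.ndarray:
        """ALT-dosage vector in sample order (-1 = missing)."""
        out = []
        for call in self.calls.values():
            if call.alleles is None:
                out.append(-1)
            else:
                out.append(sum(1 for a in call.alleles if a == alt_index))
        return np.asarray(out, dtype=int)


@dataclass(frozen=True)
class FilterConfig:
    """Cascade thresholds; ``None`` disables the corresponding filter.

    ``min_gq`` is an exclusive bound (keep GQ strictly greater), while
    ``min_dp`` and ``min_qual`` are inclusive.
    """

    min_dp: Optional[int] = 5
    min_gq: Optional[int] = 15
    min_qual: Optional[float] = 30.0
    max_f_missing: Optional[float] = None
    max_sample_missing: Optional[float] = None
    biallelic_only: bool = True
    min_fis: Optional[float] = 0.8
    require_minor_homozygote: bool = True

    def __post_init__(self) -> None:
        for frac in (self.max_f_missing, self.max_sample_missing):
            if frac is not None and not 0.0 <= frac <= 1.0:
                raise ValueError("missing-data fractions must lie in [0, 1]")


@dataclass(frozen=True)
class FilterStepReport:
    step_label: str
    n_snps: int
    tstv: Optional[float]
    n_samples: int


def _cascade_tstv(sites: Sequence[VariantSite]) -> Optional[float]:
    subs = []
    for site in sites:
        for alt in site.alts:
            if len(site.ref) == 1 and len(alt) == 1:
                subs.append((site.ref, alt))
    if not subs:
        return None
    try:
        return tstv_ratio(subs)
    except TsTvUndefined:
        return None


def mask_genotypes(sites: Sequence[VariantSite], cfg: FilterConfig) -> list[VariantSite]:
    """Step 01: mask unreliable genotypes, keeping every site.

    A call survives only with DP >= ``min_dp`` and GQ > ``min_gq``;
    calls lacking the DP or GQ tag are masked (conservative).  DP/GQ
    values are retained on masked calls.
    """
    out = []
    for site in sites:
        calls = {}
        for sample, call in site.calls.items():
            keep = not call.is_missing
            if keep and cfg.min_dp is not None:
                keep = call.dp is not None and call.dp >= cfg.min_dp
            if keep and cfg.min_gq is not None:
                keep = call.gq is not None and call.gq > cfg.min_gq
            calls[sample] = call if keep else replace(call, alleles=None)
        out.append(replace_site(site, calls=calls))
    return out


def replace_site(site: VariantSite, **kw) -> VariantSite:
    data = dict(
        chrom=site.chrom, pos=site.pos, ref=site.ref, alts=list(site.alts),
        qual=site.qual, calls=dict(site.calls), id=site.id,
    )
    data.update(kw)
    return VariantSite(**data)


def filter_loci(sites: Sequence[VariantSite], cfg: FilterConfig) -> list[VariantSite]:
    """Step 02: drop sites on QUAL and, when enabled, missing-call fraction."""
    out = []
    for site in sites:
        if cfg.min_qual is not None and site.qual < cfg.min_qual:
            continue
        if cfg.max_f_missing is not None and site.missing_fraction() > cfg.max_f_missing:
            continue
        out.append(site)
    return out


def filter_samples(
    sites: Sequence[VariantSite], cfg: FilterConfig
) -> tuple[list[VariantSite], list[str]]:
    """Step 03: remove samples with too much missing data (disabled -> identity)."""
    if cfg.max_sample_missing is None or not sites:
        return list(sites), []
    samples = list(sites[0].calls)
    missing = {s: 0 for s in samples}
    for site in sites:
        for sample, call in site.calls.items():
            if call.is_missing:
                missing[sample] += 1
    n_sites = len(sites)
    removed = [s for s in samples if missing[s] / n_sites > cfg.max_sample_missing]
    if len(removed) == len(samples):
        raise ValueError("sample filter would remove every sample")
    if not removed:
        return list(sites), []
    removed_set = set(removed)
    out = [
        replace_site(
            site,
            calls={s: c for s, c in site.calls.items() if s not in removed_set},
        )
        for site in sites
    ]
    return out, removed


def popgen_filter(
    sites: Sequence[VariantSite], cfg: FilterConfig
) -> tuple[list[VariantSite], list]:
    """Step 04: biallelic / FIS / minor-homozygote filtering.

    Sites monomorphic after masking are dropped first (FIS undefined
    there).  Returns the surviving sites and their SiteStats, aligned.
    With every popgen criterion disabled this step is the identity.
    """
    enabled = (
        cfg.biallelic_only or cfg.min_fis is not None or cfg.require_minor_homozygote
    )
    if not enabled:
        return list(sites), [None] * len(sites)
    kept: list[VariantSite] = []
    stats_out = []
    for site in sites:
        observed = site.observed_alleles()
        alt_indices = sorted(a for a in observed if a != 0)
        if len(observed) < 2:
            continue  # monomorphic after masking
        if cfg.biallelic_only and (len(alt_indices) != 1 or len(observed) > 2):
            continue
        alt_index = alt_indices[0]
        stats = site_stats_from_array(site.dosages(alt_index))
        if cfg.min_fis is not None and (stats.fis is None or stats.fis < cfg.min_fis):
            continue
        if cfg.require_minor_homozygote and stats.minor_hom_count < 1:
            continue
        kept.append(site)
        stats_out.append(stats)
    return kept, stats_out


def run_cascade(
    sites: Sequence[VariantSite], cfg: FilterConfig
) -> tuple[list[VariantSite], list[FilterStepReport]]:
    """Run steps 01..04 in order, recording SNP count and Ts/Tv after each."""
    def n_samples(current: Sequence[VariantSite]) -> int:
        return len(current[0].calls) if current else 0

    reports = []
    current = mask_genotypes(sites, cfg)
    reports.append(FilterStepReport("01", len(current), _cascade_tstv(current), n_samples(current)))
    current = filter_loci(current, cfg)
    reports.append(FilterStepReport("02", len(current), _cascade_tstv(current), n_samples(current)))
    current, _removed = filter_samples(current, cfg)
    reports.append(FilterStepReport("03", len(current), _cascade_tstv(current), n_samples(current)))
    current, _stats = popgen_filter(current, cfg)
    reports.append(FilterStepReport("04", len(current), _cascade_tstv(current), n_samples(current)))
    return current, reports


# ---------------------------------------------------------------------------
# VCF I/O

def read_vcf(path) -> tuple[list[VariantSite], list[str]]:
    """Load a VCF into sites + sample list (cyvcf2 backend)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    sites = []
    for var in vcf:
        dps = _format_ints(var, "DP", len(samples))
        gqs = _format_ints(var, "GQ", len(samples))
        calls = {}
        for i, sample in enumerate(samples):
            gt = var.genotypes[i]
            a, b = gt[0], gt[1] if len(gt) > 2 else gt[0]
            alleles = None if a < 0 or b < 0 else (a, b)
            calls[sample] = GenotypeCall(alleles=alleles, dp=dps[i], gq=gqs[i])
        sites.append(
            VariantSite(
                chrom=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alts=list(var.ALT),
                qual=float(var.QUAL) if var.QUAL is not None else 0.0,
                calls=calls,
                id=var.ID or ".",
            )
        )
    vcf.close()
    return sites, samples


def _format_ints(var, tag: str, n: int) -> list[Optional[int]]:
    try:
        arr = var.format(tag)
    except KeyError:
        arr = None
    if arr is None:
        return [None] * n
    out = []
    for v in np.asarray(arr).reshape(n, -1)[:, 0]:
        out.append(None if v < 0 else int(v))
    return out


def write_vcf(
    sites: Sequence[VariantSite],
    samples: Sequence[str],
    path,
    contigs: Optional[dict[str, int]] = None,
) -> None:
    """Write sites as a VCF 4.2 text file; masked genotypes appear as ``./.``."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for site in sites:
            cols = [
                site.chrom, str(site.pos), site.id, site.ref,
                ",".join(site.alts) or ".", f"{site.qual:g}", ".", ".", "GT:DP:GQ",
            ]
            for sample in samples:
                call = site.calls.get(sample, GenotypeCall(None))
                gt = "./." if call.alleles is None else f"{call.alleles[0]}/{call.alleles[1]}"
                dp = "." if call.dp is None else str(call.dp)
                gq = "." if call.gq is None else str(call.gq)
                cols.append(f"{gt}:{dp}:{gq}")
            fh.write("\t".join(cols) + "\n")


def write_step_reports(reports: Sequence[FilterStepReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("step\tn_snps\ttstv\tn_samples\n")
        for rep in reports:
            tstv = "NA" if rep.tstv is None else f"{rep.tstv:.4f}"
            fh.write(f"{rep.step_label}\t{rep.n_snps}\t{tstv}\t{rep.n_samples}\n")
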