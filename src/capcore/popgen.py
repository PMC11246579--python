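"""Per-site and per-population statistics for filtering, QC and diversity scans.

All statistics operate on biallelic diploid genotype calls.  Per site:

* ``p``   — ALT allele frequency among non-missing calls,
* ``He``  — Nei's expected heterozygosity ``2 p (1 - p)``,
* ``Ho``  — observed heterozygote fraction,
* ``FIS`` — inbreeding coefficient ``1 - Ho / He`` (undefined when the
  site is monomorphic), clipped to [-1, 1].

At selfing equilibrium with outcrossing rate ``t`` the expected FIS is
Weir's ``(1 - t) / (1 + t)`` — near 1 for a predominant selfer like
durum wheat, which is what makes excess heterozygosity (low FIS) a
useful artefact signal.

Population differentiation uses the Weir & Cockerham (1984) theta
estimator with ratio-of-sums aggregation over sites; nucleotide
diversity pi uses the unbiased ``2n/(2n-1)`` small-sample correction;
and the Fst scan flags zones whose Fst lies strictly above the
chromosome-wide 95% quantile.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "SiteStats",
    "PopAssignment",
    "DiversitySummary",
    "TsTvUndefined",
    "site_stats",
    "site_stats_from_array",
    "expected_fis_selfing",
    "tstv_ratio",
    "is_transition",
    "nucleotide_diversity",
    "dri",
    "pairwise_fst",
    "wc_fst_components",
    "fst_scan",
    "mean_depth_per_zone_per_sample",
]

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class TsTvUndefined(ZeroDivisionError):
    """Raised when a Ts/Tv ratio has zero transversions in the denominator."""


@dataclass(frozen=True)
class SiteStats:
    """Summary of one biallelic site over its genotyped individuals."""

    n: int  # genotyped diploid individuals
    p: float  # ALT allele frequency
    he: float
    ho: float
    fis: Optional[float]  # None when He == 0
    maf: float
    minor_hom_count: int


@dataclass
class PopAssignment:
    """Sample-to-population map with the per-population sample floor."""

    assignment: Mapping[str, str]
    min_per_pop: int = 10

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in self.assignment.items() if p == population]


@dataclass(frozen=True)
class DiversitySummary:
    population: str
    pi: float  # mean per-site nucleotide diversity
    n_sites: int


# genotype encoding used throughout: per-individual ALT dosage
# 0 = hom REF, 1 = het, 2 = hom ALT, -1 = missing
def _dosages(calls) -> np.ndarray:
    arr = np.asarray(calls, dtype=int)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D dosage vector")
    return arr


def site_stats_from_array(dosages: Sequence[int]) -> SiteStats:
    """Site statistics from a vector of ALT dosages (-1 = missing)."""
    arr = _dosages(dosages)
    obs = arr[arr >= 0]
    n = obs.size
    if n == 0:
        raise ValueError("no genotyped individuals at this site")
    p = float(obs.sum()) / (2 * n)
    he = 2.0 * p * (1.0 - p)
    ho = float(np.count_nonzero(obs == 1)) / n
    if he > 0:
        fis = min(1.0, max(-1.0, 1.0 - ho / he))
    else:
        fis = None
    maf = min(p, 1.0 - p)
    # on an exact 50/50 tie the ALT allele counts as minor
    minor_dosage = 2 if p <= 0.5 else 0
    minor_hom = int(np.count_nonzero(obs == minor_dosage))
    return SiteStats(n=n, p=p, he=he, ho=ho, fis=fis, maf=maf, minor_hom_count=minor_hom)


def site_stats(calls: Mapping[str, object]) -> SiteStats:
    """Site statistics from sample -> GenotypeCall-like mapping.

    Accepts any objects exposing ``alleles`` as a pair of 0/1 integers
    or ``None`` for missing.
    """
    dosages = []
    for call in calls.values():
        alleles = getattr(call, "alleles", call)
        if alleles is None:
            dosages.append(-1)
        else:
            a, b = alleles
            dosages.append(int(a) + int(b))
    return site_stats_from_array(dosages)


def expected_fis_selfing(t: float) -> float:
    """Equilibrium inbreeding coefficient (1 - t)/(1 + t) at outcrossing rate t."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"outcrossing rate must be in [0, 1], got {t}")
    return (1.0 - t) / (1.0 + t)


def is_transition(ref: str, alt: str) -> bool:
    """A<->G and C<->T are transitions; the four other classes transversions."""
    return (ref.upper(), alt.upper()) in TRANSITIONS


def tstv_ratio(substitutions: Sequence[tuple[str, str]]) -> float:
    """Ts/Tv over (REF, ALT) single-base substitutions.

    Raises :class:`TsTvUndefined` when no transversion is present, so an
    infinite ratio never propagates silently.
    """
    ts = tv = 0
    for ref, alt in substitutions:
        if len(ref) != 1 or len(alt) != 1:
            raise ValueError(f"not a single-base substitution: {ref}>{alt}")
        if is_transition(ref, alt):
            ts += 1
        else:
            tv += 1
    if tv == 0:
        raise TsTvUndefined(f"{ts} transitions but zero transversions")
    return ts / tv


def nucleotide_diversity(
    site_dosages: Sequence[Sequence[int]],
    pop: PopAssignment,
    population: str,
    samples: Sequence[str],
) -> DiversitySummary:
    """Mean per-site nucleotide diversity within one population.

    Per qualifying site (>= ``pop.min_per_pop`` genotyped individuals in
    the population), pi_i = 2n/(2n-1) * 2 p (1-p); sites failing the
    floor are excluded from the mean.
    """
    members = set(pop.samples_in(population))
    idx = [i for i, s in enumerate(samples) if s in members]
    if not idx:
        raise ValueError(f"no samples assigned to population {population!r}")
    pis = []
    for dosages in site_dosages:
        arr = _dosages(dosages)[idx]
        obs = arr[arr >= 0]
        n = obs.size
        if n < pop.min_per_pop:
            continue
        p = float(obs.sum()) / (2 * n)
        pis.append((2 * n) / (2 * n - 1) * 2.0 * p * (1.0 - p))
    if not pis:
        raise ValueError(f"no site with >= {pop.min_per_pop} genotyped individuals")
    return DiversitySummary(population=population, pi=float(np.mean(pis)), n_sites=len(pis))


def dri(pi_ancestral: float, pi_derived: float) -> float:
    """Diversity Reduction Index: ancestral pi over derived pi.

    A bottleneck in the derived population lowers its diversity, so a
    stronger loss gives a larger DRI (> 1).
    """
    if pi_derived <= 0:
        raise ValueError("derived-population diversity must be > 0")
    return pi_ancestral / pi_derived


def wc_fst_components(
    n_a: int, p_a: float, h_a: float, n_b: int, p_b: float, h_b: float
) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) variance components (a, b, c) for one site.

    ``n_*`` genotyped diploids, ``p_*`` ALT frequencies, ``h_*``
    observed heterozygote fractions in the two populations.
    """
    r = 2
    n_bar = (n_a + n_b) / r
    if n_bar <= 1:
        raise ValueError("need more than one individual per population on average")
    n_c = (r * n_bar - (n_a**2 + n_b**2) / (r * n_bar)) / (r - 1)
    p_bar = (n_a * p_a + n_b * p_b) / (r * n_bar)
    s2 = (n_a * (p_a - p_bar) ** 2 + n_b * (p_b - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n_a * h_a + n_b * h_b) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    return a, b, c


def pairwise_fst(
    site_dosages: Sequence[Sequence[int]],
    pop: PopAssignment,
    pop_a: str,
    pop_b: str,
    samples: Sequence[str],
) -> float:
    """Multi-site Weir & Cockerham theta between two populations.

    Aggregation is ratio-of-sums: theta = sum(a) / sum(a + b + c) over
    qualifying sites (>= ``pop.min_per_pop`` genotyped individuals in
    each population).  Negative estimates are reported as-is.
    """
    idx_a = [i for i, s in enumerate(samples) if pop.assignment.get(s) == pop_a]
    idx_b = [i for i, s in enumerate(samples) if pop.assignment.get(s) == pop_b]
    if not idx_a or not idx_b:
        raise ValueError(f"populations {pop_a!r}/{pop_b!r} not found in assignment")

    num = den = 0.0
    n_used = 0
    for dosages in site_dosages:
        arr = _dosages(dosages)
        obs_a = arr[idx_a][arr[idx_a] >= 0]
        obs_b = arr[idx_b][arr[idx_b] >= 0]
        if obs_a.size < pop.min_per_pop or obs_b.size < pop.min_per_pop:
            continue
        p_a = float(obs_a.sum()) / (2 * obs_a.size)
        p_b = float(obs_b.sum()) / (2 * obs_b.size)
        if p_a in (0.0, 1.0) and p_b == p_a:
            continue  # monomorphic across both populations: no information
        h_a = float(np.count_nonzero(obs_a == 1)) / obs_a.size
        h_b = float(np.count_nonzero(obs_b == 1)) / obs_b.size
        a, b, c = wc_fst_components(obs_a.size, p_a, h_a, obs_b.size, p_b, h_b)
        num += a
        den += a + b + c
        n_used += 1
    if n_used == 0 or den == 0.0:
        raise ValueError("no polymorphic site qualifies for the Fst estimate")
    return num / den


def fst_scan(
    zone_values: Mapping[str, Mapping[str, float]], q: float = 0.95
) -> tuple[dict[str, float], dict[str, list[str]]]:
    """Chromosome-wise outlier scan over per-zone Fst values.

    ``zone_values`` maps chromosome -> {zone name -> Fst (NaN allowed)}.
    Per chromosome the threshold is the empirical ``q`` quantile (linear
    interpolation between order statistics); outliers are zones with Fst
    *strictly* above it.  Chromosomes without >= 2 defined values are
    skipped with a warning.
    """
    thresholds: dict[str, float] = {}
    outliers: dict[str, list[str]] = {}
    for chrom, per_zone in zone_values.items():
        defined = {z: v for z, v in per_zone.items() if v is not None and math.isfinite(v)}
        if len(defined) < 2:
            warnings.warn(f"chromosome {chrom}: fewer than two defined Fst values; skipped")
            continue
        values = np.array(list(defined.values()))
        threshold = float(np.quantile(values, q))  # numpy default = type 7
        thresholds[chrom] = threshold
        outliers[chrom] = sorted(z for z, v in defined.items() if v > threshold)
    return thresholds, outliers


def mean_depth_per_zone_per_sample(
    per_sample_depths: Mapping[str, Mapping[str, Sequence[float]]],
    zones: Sequence,
):
    """Mean per-base depth of each sample within each zone.

    ``per_sample_depths`` maps sample -> chromosome -> per-base depths.
    Returns a pandas DataFrame with one row per zone, one column per
    sample (the 'mean_depth_per_zone_per_sample' report layout).
    """
    import pandas as pd

    table: dict[str, list[float]] = {}
    index = [z.name for z in zones]
    for sample, chrom_depths in per_sample_depths.items():
        col = []
        for zone in zones:
            if zone.chrom not in chrom_depths:
                raise KeyError(f"sample {sample}: no depths for {zone.chrom}")
            depths = np.asarray(chrom_depths[zone.chrom], dtype=float)
            if zone.end > depths.shape[0]:
                raise ValueError(f"zone {zone.name} outside depth range of {sample}")
            col.append(float(depths[zone.start : zone.end].mean()))
        table[sample] = col
    return pd.DataFrame(table, index=index)
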