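import numpy as np
import pytest

from capcore import SimulationConfig, simulate_alignments, simulate_reference


def zones_bruteforce(depth, min_mean_cov, min_dist, min_length):
    """Independent per-base oracle for coverage-driven zone calling.

    Chains marked bases pairwise: two consecutive marked bases belong to
    the same region when the unmarked gap between them is strictly
    shorter than ``min_dist``; regions shorter than ``min_length`` are
    discarded.
    """
    marked = [i for i, d in enumerate(depth) if d >= min_mean_cov]
    if not marked:
        return []
    regions = [[marked[0], marked[0] + 1]]
    for prev, cur in zip(marked, marked[1:]):
        gap = cur - prev - 1
        if gap == 0 or gap < min_dist:
            regions[-1][1] = cur + 1
        else:
            regions.append([cur, cur + 1])
    return [(s, e) for s, e in regions if e - s >= min_length]


@pytest.fixture(scope="session")
def capture_sim():
    """One shared capture simulation: reference, zones, alignments, truth."""
    cfg = SimulationConfig(seed=42, n_samples=2, n_pairs_per_sample=300)
    reference, zones = simulate_reference(cfg)
    records, truth = simulate_alignments(cfg, reference, zones)
    return cfg, reference, zones, records, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
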