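"""Shared fixtures: locus profiles, small benchmarks, fast configs."""

from __future__ import annotations

import numpy as np
import pytest

from vexscan import RunConfig
from vexscan.config import LOCI
from vexscan.synthetic import BenchmarkConfig, build_benchmark, \
    make_locus_profiles, sample_family


@pytest.fixture(scope="session")
def profiles():
    return make_locus_profiles(seed=11)


@pytest.fixture(scope="session")
def small_benchmark(profiles):
    """Tiny benchmark: 2 tier-0 exons per locus + 8 decoys on 2 contigs."""
    cfg = BenchmarkConfig(n_per_locus_per_tier={0: 2}, n_decoys=8,
                          n_contigs=2, contig_length=12000, seed=21)
    return build_benchmark(cfg, profiles)


@pytest.fixture(scope="session")
def tier0_training(profiles):
    """Seed training families (disjoint seed from any benchmark)."""
    return {k: sample_family(profiles[k], 12, tier=0, seed=501)
            for k in LOCI}


@pytest.fixture()
def fast_config():
    """Small forests for unit-level behavior tests."""
    return RunConfig(n_trees=40, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
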