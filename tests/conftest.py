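"""Shared fixtures: a small simulated cohort reused across unit tests.

Hypothesis runs derandomized so the suite is reproducible bit-for-bit.
"""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from svlineage import simulate

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


SMALL_REPEATS = simulate.RepeatConfig(tandem_array_count=60, dispersed_repeat_count=8)


@pytest.fixture(scope="session")
def small_cohort():
    """1 Mb, 2-chromosome, 5-line cohort at a reduced event rate.  (Below
    ~1 Mb the 12-30 kb inversions cannot reliably find a clear window among
    the other planted loci.)"""
    ancestor, features = simulate.simulate_ancestor(
        1_000_000, n_chroms=2, repeat_config=SMALL_REPEATS, seed=11
    )
    tree = simulate.LineTree.default()
    genomes, truth = simulate.plant_svs(
        ancestor, features, tree, rate_per_branch=6.0, seed=12
    )
    return ancestor, features, tree, genomes, truth


@pytest.fixture(scope="session")
def small_line(small_cohort):
    """One line genome plus its truth records, for alignment/calling tests."""
    ancestor, _, _, genomes, truth = small_cohort
    line = sorted(genomes)[0]
    return ancestor, genomes[line], truth.for_line(line)


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
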