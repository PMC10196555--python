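"""Shared fixtures: fitness tables, tag schemes, references."""

import numpy as np
import pytest

from btrefuge.popgen import build_fitness_table
from btrefuge.synth import make_reference, make_tag_scheme


@pytest.fixture(scope="session")
def field_table():
    """Empirical fitness table (incomplete resistance as rr fitness on Bt)."""
    return build_fitness_table()


@pytest.fixture(scope="session")
def ratio_table():
    """Fitness table with incomplete resistance read as a Bt/non-Bt ratio."""
    return build_fitness_table(incomplete_resistance_mode="ratio")


@pytest.fixture(scope="session")
def reference():
    return make_reference(seed=11)


@pytest.fixture(scope="session")
def three_site_scheme():
    return make_tag_scheme(
        [("siteA", 50, 2016), ("siteB", 80, 2016), ("siteC", 100, 2016)],
        seed=5,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def selection_oracle(p, w):
    """Independent oracle: explicit genotype enumeration and weighting.

    Forms the Hardy-Weinberg genotype frequencies, weights each genotype by
    its fitness, renormalises, and reads off the allele frequency from the
    surviving genotype distribution.
    """
    q = 1.0 - p
    weighted = np.array([q * q * w[0], 2 * p * q * w[1], p * p * w[2]])
    geno = weighted / weighted.sum()
    return geno[2] + 0.5 * geno[1]
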