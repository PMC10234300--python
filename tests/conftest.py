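import numpy as np
import pytest

from triosel.datatypes import Haplotype, Individual, SiteList, Trio, TrioCohort
from triosel.recomb import RecombinationMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sites5():
    return SiteList(np.array(["1"] * 5, dtype=object), np.arange(5) * 1000)


def make_individual(sites, iid, sex, hap1_bits, hap2_bits):
    return Individual(
        iid,
        sex,
        Haplotype(sites, np.array(hap1_bits, dtype=bool)),
        Haplotype(sites, np.array(hap2_bits, dtype=bool)),
    )


@pytest.fixture
def small_trio(sites5):
    mother = make_individual(sites5, "m0", "female", [1, 0, 1, 0, 0], [0, 1, 0, 0, 0])
    father = make_individual(sites5, "d0", "male", [0, 0, 1, 1, 0], [1, 0, 0, 0, 0])
    child = make_individual(sites5, "c0", "male", [1, 0, 1, 0, 0], [0, 0, 1, 1, 0])
    return Trio(mother, father, child, 1)


@pytest.fixture
def small_cohort(small_trio, sites5):
    return TrioCohort([small_trio], sites5)


@pytest.fixture
def flat_maps():
    fmap = RecombinationMap.uniform("female", "1", 1_000_000, 1.0)
    mmap = RecombinationMap.uniform("male", "1", 1_000_000, 1.0)
    return fmap, mmap
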