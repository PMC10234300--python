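"""Summary statistics: mean genotype counts and their parent/offspring deltas."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .datatypes import GenotypeCounts, Individual, TrioCohort

__all__ = [
    "MeanCounts",
    "SummaryVector",
    "mean_counts",
    "summary_vector",
    "parental_means",
    "offspring_means",
    "observed_summary",
]


@dataclass(frozen=True)
class MeanCounts:
    mean_homo: float
    mean_het: float
    n_individuals: int

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("MeanCounts requires at least one individual")


@dataclass(frozen=True)
class SummaryVector:
    """(delta_homo, delta_het): offspring-minus-parent mean genotype counts."""

    delta_homo: float
    delta_het: float

    def as_array(self) -> np.ndarray:
        return np.array([self.delta_homo, self.delta_het], dtype=np.float64)


def mean_counts(counts: Sequence[GenotypeCounts]) -> MeanCounts:
    if len(counts) == 0:
        raise ValueError("cannot average an empty set of individuals")
    kh = np.array([c.k_homo for c in counts], dtype=np.float64)
    kt = np.array([c.k_het for c in counts], dtype=np.float64)
    return MeanCounts(float(kh.mean()), float(kt.mean()), len(counts))


def summary_vector(offspring: MeanCounts, parents: MeanCounts) -> SummaryVector:
    return SummaryVector(
        offspring.mean_homo - parents.mean_homo,
        offspring.mean_het - parents.mean_het,
    )


def _means_of(individuals: Iterable[Individual]) -> MeanCounts:
    return mean_counts([ind.genotype_counts() for ind in individuals])


def parental_means(cohort: TrioCohort) -> MeanCounts:
    """Mean counts over the parental generation, each unique parent once."""
    return _means_of(cohort.unique_parents())


def offspring_means(cohort: TrioCohort) -> MeanCounts:
    return _means_of(cohort.children())


def observed_summary(cohort: TrioCohort) -> SummaryVector:
    return summary_vector(offspring_means(cohort), parental_means(cohort))
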