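"""Core domain types: sites, haplotypes, individuals, trios, cohorts.

Coordinates are 0-based half-open internally; VCF positions are converted
on read.  A haplotype is a boolean carrier vector over the cohort's shared
candidate-site list (``True`` = carries the derived allele).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Sequence

import numpy as np

Sex = Literal["female", "male"]

__all__ = [
    "SiteList",
    "Haplotype",
    "GenotypeCounts",
    "Individual",
    "Trio",
    "TrioCohort",
    "SelectionParams",
]


@dataclass(frozen=True)
class SiteList:
    """Shared list of candidate sites (biallelic SNPs), ordered by (chrom, pos)."""

    chrom: np.ndarray  # dtype object/str, shape (n,)
    pos: np.ndarray  # int64, 0-based, shape (n,)

    def __post_init__(self) -> None:
        chrom = np.asarray(self.chrom, dtype=object)
        pos = np.asarray(self.pos, dtype=np.int64)
        if chrom.shape != pos.shape:
            raise ValueError("chrom and pos must have equal length")
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "pos", pos)
        # positions strictly increasing within each chromosome
        for c in self.chromosomes():
            p = pos[chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    def __len__(self) -> int:
        return len(self.pos)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous index slice per chromosome (sites are grouped by chrom)."""
        out: dict[str, slice] = {}
        start = 0
        chrom = self.chrom
        for i in range(1, len(self) + 1):
            if i == len(self) or chrom[i] != chrom[start]:
                out[str(chrom[start])] = slice(start, i)
                start = i
        return out

    def subset(self, indices: Sequence[int]) -> "SiteList":
        idx = np.asarray(indices, dtype=np.int64)
        return SiteList(self.chrom[idx], self.pos[idx])


@dataclass(frozen=True)
class Haplotype:
    """Carrier vector of the derived allele over a shared candidate-site list."""

    sites: SiteList
    carriers: np.ndarray  # bool, shape (len(sites),)

    def __post_init__(self) -> None:
        carriers = np.asarray(self.carriers, dtype=bool)
        if carriers.shape != (len(self.sites),):
            raise ValueError("carrier vector length must match site list")
        object.__setattr__(self, "carriers", carriers)

    def carried_indices(self) -> np.ndarray:
        return np.flatnonzero(self.carriers)

    def n_carried(self) -> int:
        return int(self.carriers.sum())


@dataclass(frozen=True)
class GenotypeCounts:
    """Counts of candidate sites homozygous / heterozygous for the derived allele."""

    k_homo: int
    k_het: int

    def __post_init__(self) -> None:
        if self.k_homo < 0 or self.k_het < 0:
            raise ValueError("genotype counts must be non-negative")

    def __add__(self, other: "GenotypeCounts") -> "GenotypeCounts":
        return GenotypeCounts(self.k_homo + other.k_homo, self.k_het + other.k_het)


@dataclass(frozen=True)
class Individual:
    id: str
    sex: Sex
    hap1: Haplotype
    hap2: Haplotype

    def __post_init__(self) -> None:
        if self.hap1.sites is not self.hap2.sites and len(self.hap1.sites) != len(
            self.hap2.sites
        ):
            raise ValueError("both haplotypes must index the same candidate-site list")

    def genotype_counts(self) -> GenotypeCounts:
        a, b = self.hap1.carriers, self.hap2.carriers
        return GenotypeCounts(int((a & b).sum()), int((a ^ b).sum()))

    def carries(self) -> np.ndarray:
        """Bool vector: carries the derived allele on at least one haplotype."""
        return self.hap1.carriers | self.hap2.carriers

    def is_het(self, site_index: int) -> bool:
        return bool(self.hap1.carriers[site_index] != self.hap2.carriers[site_index])


@dataclass(frozen=True)
class Trio:
    mother: Individual
    father: Individual
    child: Individual
    n_children_of_couple: int = 1

    def __post_init__(self) -> None:
        if self.n_children_of_couple < 1:
            raise ValueError("n_children_of_couple must be positive")
        if self.mother.sex != "female" or self.father.sex != "male":
            raise ValueError("mother must be female and father male")

    @property
    def couple_id(self) -> tuple[str, str]:
        return (self.mother.id, self.father.id)


@dataclass
class TrioCohort:
    trios: list[Trio]
    candidate_sites: SiteList

    @property
    def n(self) -> int:
        return len(self.trios)

    def children(self) -> list[Individual]:
        return [t.child for t in self.trios]

    def unique_parents(self) -> list[Individual]:
        """Each parent once, even when present in multiple trios."""
        seen: dict[str, Individual] = {}
        for t in self.trios:
            for p in (t.mother, t.father):
                seen.setdefault(p.id, p)
        return list(seen.values())

    def couples(self) -> list[tuple[tuple[str, str], list[Trio]]]:
        """Trios grouped by couple, preserving first-appearance order."""
        groups: dict[tuple[str, str], list[Trio]] = {}
        for t in self.trios:
            groups.setdefault(t.couple_id, []).append(t)
        return list(groups.items())

    def subset_sites(self, indices: Sequence[int]) -> "TrioCohort":
        idx = np.asarray(indices, dtype=np.int64)
        sites = self.candidate_sites.subset(idx)

        def cut(ind: Individual) -> Individual:
            return Individual(
                ind.id,
                ind.sex,
                Haplotype(sites, ind.hap1.carriers[idx]),
                Haplotype(sites, ind.hap2.carriers[idx]),
            )

        new_trios = [
            Trio(cut(t.mother), cut(t.father), cut(t.child), t.n_children_of_couple)
            for t in self.trios
        ]
        return TrioCohort(new_trios, sites)

    def __iter__(self) -> Iterator[Trio]:
        return iter(self.trios)


@dataclass(frozen=True)
class SelectionParams:
    """Selection coefficient s and dominance coefficient h.

    Fitness of a genotype is multiplicative over sites: each homozygous-derived
    site contributes a factor (1 + s) and each heterozygous site (1 + h*s),
    so validity requires 1 + s > 0 and 1 + h*s > 0.
    """

    s: float
    h: float

    def __post_init__(self) -> None:
        if 1.0 + self.s <= 0.0:
            raise ValueError(f"invalid selection coefficient s={self.s}: 1+s must be > 0")
        if 1.0 + self.h * self.s <= 0.0:
            raise ValueError(
                f"invalid (s, h)=({self.s}, {self.h}): 1+h*s must be > 0"
            )
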