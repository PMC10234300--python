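"""Meiosis simulation: crossovers, gametes, and per-couple zygote arrays.

The zygote arrays are the engine room of the method: for every couple we
pre-simulate a fixed number of potential offspring (default 150), reduced to
(k_homo, k_het) genotype counts over the candidate sites.  Selection is later
imposed by sampling zygotes with probability proportional to fitness, so the
arrays are built once and reused across all ABC iterations.

Crossovers follow a no-interference model: the count per meiosis is Poisson
with mean equal to the map length in Morgans, and positions are drawn by
inverse CDF on the cumulative map (density proportional to local cM/bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .datatypes import GenotypeCounts, Haplotype, Individual, SiteList, TrioCohort
from .recomb import RecombinationMap

__all__ = [
    "DeNovoConfig",
    "Zygote",
    "ZygoteArray",
    "ZygoteArrays",
    "sample_crossovers",
    "make_gamete",
    "build_zygote_arrays",
    "strip_de_novo",
]

DEFAULT_ZYGOTES_PER_TRIO = 150


@dataclass(frozen=True)
class DeNovoConfig:
    """Poisson de novo mutation model: mean count per zygote is L * mu."""

    L: int = 0
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.L < 0 or self.mu < 0:
            raise ValueError("L and mu must be non-negative")

    @property
    def rate(self) -> float:
        return self.L * self.mu


@dataclass(frozen=True)
class Zygote:
    counts: GenotypeCounts
    genotype: Optional[int] = None  # derived-allele copies at the focal site (single-SNP mode)


@dataclass
class ZygoteArray:
    """Fixed-size set of potential zygotes for one couple."""

    couple_id: tuple[str, str]
    k_homo: np.ndarray  # int32, shape (Z,)
    k_het: np.ndarray  # int32, shape (Z,)
    n_children: int = 1

    def __post_init__(self) -> None:
        if len(self.k_homo) < 1:
            raise ValueError("zygote array must contain at least one zygote")
        if len(self.k_homo) != len(self.k_het):
            raise ValueError("k_homo and k_het must have equal length")

    def __len__(self) -> int:
        return len(self.k_homo)

    def zygote(self, j: int, single_site: bool = False) -> Zygote:
        counts = GenotypeCounts(int(self.k_homo[j]), int(self.k_het[j]))
        geno = 2 * counts.k_homo + counts.k_het if single_site else None
        return Zygote(counts, geno)


@dataclass
class ZygoteArrays:
    """Stacked zygote arrays for a cohort (one row block per couple)."""

    sites: SiteList
    couple_ids: list[tuple[str, str]]
    KH: np.ndarray  # int32 (n_couples, Z)
    KT: np.ndarray  # int32 (n_couples, Z)
    n_children: np.ndarray  # int64 (n_couples,)
    single_site: bool = False

    @property
    def n_couples(self) -> int:
        return self.KH.shape[0]

    @property
    def zygotes_per_trio(self) -> int:
        return self.KH.shape[1]

    @property
    def total_children(self) -> int:
        return int(self.n_children.sum())

    def __iter__(self):
        for i, cid in enumerate(self.couple_ids):
            yield ZygoteArray(cid, self.KH[i], self.KT[i], int(self.n_children[i]))

    def __getitem__(self, i: int) -> ZygoteArray:
        return ZygoteArray(
            self.couple_ids[i], self.KH[i], self.KT[i], int(self.n_children[i])
        )


def sample_crossovers(
    recmap: RecombinationMap, chrom: str, rng: np.random.Generator
) -> np.ndarray:
    """Crossover bp positions for one meiosis on one chromosome, sorted ascending."""
    morgans = recmap.total_cm(chrom) / 100.0
    n = rng.poisson(morgans)
    if n == 0:
        return np.empty(0, dtype=np.float64)
    return np.sort(recmap.sample_positions(chrom, n, rng))


def make_gamete(
    hapA: Haplotype,
    hapB: Haplotype,
    crossovers: np.ndarray,
    start: Literal["A", "B"],
) -> Haplotype:
    """Assemble a gamete by alternating between two haplotypes at crossovers.

    The allele at each site comes from the starting haplotype if an even
    number of crossovers lie at positions <= the site, else from the other.
    """
    sites = hapA.sites
    crossovers = np.asarray(crossovers, dtype=np.float64)
    parity = np.searchsorted(crossovers, sites.pos, side="right") % 2
    use_second = parity == 1 if start == "A" else parity == 0
    carriers = np.where(use_second, hapB.carriers, hapA.carriers)
    return Haplotype(sites, carriers)


def _gamete_alleles_block(
    hap1: np.ndarray,
    hap2: np.ndarray,
    pos: np.ndarray,
    recmap: RecombinationMap,
    chrom: str,
    n_gametes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Alleles at `pos` for n_gametes independent meioses (vectorized).

    hap1/hap2 are carrier bools at `pos` (one chromosome).  Returns a bool
    matrix (n_gametes, len(pos)).
    """
    morgans = recmap.total_cm(chrom) / 100.0
    counts = rng.poisson(morgans, size=n_gametes)
    start = rng.integers(0, 2, size=n_gametes)
    maxc = int(counts.max()) if n_gametes else 0
    if maxc == 0:
        parity = np.zeros((n_gametes, len(pos)), dtype=np.int64)
    else:
        cx = recmap.sample_positions(chrom, n_gametes * maxc, rng).reshape(
            n_gametes, maxc
        )
        cx[np.arange(maxc)[None, :] >= counts[:, None]] = np.inf
        parity = (cx[:, :, None] <= pos[None, None, :]).sum(axis=1)
    use_second = (parity + start[:, None]) % 2 == 1
    return np.where(use_second, hap2[None, :], hap1[None, :])


def _couple_zygote_counts(
    mother: Individual,
    father: Individual,
    sites: SiteList,
    female_map: RecombinationMap,
    male_map: RecombinationMap,
    n_zygotes: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """(k_homo, k_het) for n_zygotes simulated zygotes of one couple.

    Only sites carried by at least one parental haplotype can appear in a
    gamete, so the simulation is restricted to that union (sparse in the
    exome-scale regime).
    """
    union = np.flatnonzero(
        mother.hap1.carriers
        | mother.hap2.carriers
        | father.hap1.carriers
        | father.hap2.carriers
    )
    if len(union) == 0:
        z = np.zeros(n_zygotes, dtype=np.int32)
        return z, z.copy()

    mat_blocks, pat_blocks = [], []
    for chrom, sl in sites.chrom_slices().items():
        in_chrom = union[(union >= sl.start) & (union < sl.stop)]
        if len(in_chrom) == 0:
            continue
        pos = sites.pos[in_chrom].astype(np.float64)
        mat_blocks.append(
            _gamete_alleles_block(
                mother.hap1.carriers[in_chrom],
                mother.hap2.carriers[in_chrom],
                pos, female_map, chrom, n_zygotes, rng,
            )
        )
        pat_blocks.append(
            _gamete_alleles_block(
                father.hap1.carriers[in_chrom],
                father.hap2.carriers[in_chrom],
                pos, male_map, chrom, n_zygotes, rng,
            )
        )
    M = np.concatenate(mat_blocks, axis=1)
    P = np.concatenate(pat_blocks, axis=1)
    k_homo = (M & P).sum(axis=1).astype(np.int32)
    k_het = (M ^ P).sum(axis=1).astype(np.int32)
    return k_homo, k_het


def build_zygote_arrays(
    cohort: TrioCohort,
    female_map: RecombinationMap,
    male_map: RecombinationMap,
    zygotes_per_trio: int = DEFAULT_ZYGOTES_PER_TRIO,
    denovo: DeNovoConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> ZygoteArrays:
    """Pre-simulate one shared zygote array per couple.

    Couples with c observed children get a single array from which c zygotes
    are drawn (with replacement) per ABC iteration.  Each zygote combines a
    maternal gamete (female map) and a paternal gamete (male map); de novo
    mutations, if configured, add an independent Poisson(L*mu) count to k_het.

    Randomness is split into per-couple substreams derived from the master
    seed, so rebuilding with the same seed reproduces the arrays exactly.
    """
    if zygotes_per_trio < 1:
        raise ValueError("zygotes_per_trio must be >= 1")
    if isinstance(seed, np.random.Generator):
        seed = int(seed.integers(2**63))
    root = np.random.SeedSequence(seed)

    couples = cohort.couples()
    n_c = len(couples)
    sites = cohort.candidate_sites
    single_site = len(sites) == 1

    KH = np.zeros((n_c, zygotes_per_trio), dtype=np.int32)
    KT = np.zeros((n_c, zygotes_per_trio), dtype=np.int32)
    n_children = np.array([len(ts) for _, ts in couples], dtype=np.int64)
    couple_ids = [cid for cid, _ in couples]
    streams = root.spawn(n_c)

    if single_site:
        # One site: recombination cannot shuffle anything, so transmission is a
        # fair coin between the two parental haplotypes.
        m1 = np.array([ts[0].mother.hap1.carriers[0] for _, ts in couples])
        m2 = np.array([ts[0].mother.hap2.carriers[0] for _, ts in couples])
        f1 = np.array([ts[0].father.hap1.carriers[0] for _, ts in couples])
        f2 = np.array([ts[0].father.hap2.carriers[0] for _, ts in couples])
        rng = np.random.default_rng(root.spawn(1)[0])
        pick_m = rng.integers(0, 2, size=(n_c, zygotes_per_trio)).astype(bool)
        pick_f = rng.integers(0, 2, size=(n_c, zygotes_per_trio)).astype(bool)
        mg = np.where(pick_m, m2[:, None], m1[:, None])
        pg = np.where(pick_f, f2[:, None], f1[:, None])
        KH = (mg & pg).astype(np.int32)
        KT = (mg ^ pg).astype(np.int32)
    else:
        for i, (_, trios) in enumerate(couples):
            rng = np.random.default_rng(streams[i])
            KH[i], KT[i] = _couple_zygote_counts(
                trios[0].mother,
                trios[0].father,
                sites,
                female_map,
                male_map,
                zygotes_per_trio,
                rng,
            )

    if denovo is not None and denovo.rate > 0:
        rng = np.random.default_rng(root.spawn(1 + n_c)[-1])
        KT = KT + rng.poisson(denovo.rate, size=KT.shape).astype(np.int32)
        single_site = False  # k_het can now exceed 1 even with one candidate site

    return ZygoteArrays(sites, couple_ids, KH, KT, n_children, single_site)


def strip_de_novo(child: Individual, mother: Individual, father: Individual) -> Individual:
    """Remove child-carried sites absent from both parents (untransmitted)."""
    parental = mother.carries() | father.carries()
    sites = child.hap1.sites
    return Individual(
        child.id,
        child.sex,
        Haplotype(sites, child.hap1.carriers & parental),
        Haplotype(sites, child.hap2.carriers & parental),
    )
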