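"""Synthetic trio cohorts for validation and benchmarking.

Generators cover the method's test scenarios: single-SNP Bernoulli cohorts,
a maximal-LD block of 11 SNPs, a compact Wright-Fisher forward simulator
with an optional gamma DFE, and a mate-and-select step that produces trio
cohorts by viability selection on simulated embryos.  All generators are
seed-deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import Haplotype, Individual, SiteList, Trio, TrioCohort
from .meiosis import make_gamete, sample_crossovers
from .recomb import RecombinationMap

logger = logging.getLogger(__name__)

__all__ = [
    "SingleSnpScenario",
    "LDBlockScenario",
    "GammaDFE",
    "Epoch",
    "DemographyModel",
    "gen_single_snp",
    "gen_ld_block",
    "gen_burden_parents",
    "forward_wf",
    "mate_and_select",
    "gamma_dfe_mean",
    "recovery_report",
    "default_maps",
]


# ---------------------------------------------------------------------------
# scenario definitions


@dataclass(frozen=True)
class SingleSnpScenario:
    n_trios: int
    q: float = 0.5
    s_true: float = 0.0
    h_true: float = 0.0
    avoid_double_homo: bool = True
    survival_shift: float = 0.0  # subtract from fitness before the survival trial

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError("allele frequency q must lie strictly in (0, 1)")
        if self.n_trios < 1:
            raise ValueError("n_trios must be positive")


@dataclass(frozen=True)
class LDBlockScenario:
    n_snps: int = 11
    spacing_bp: int = 1000
    focal_index: int = 6  # 1-based, middle SNP
    focal_s: float = -0.1
    neighbor_s: float = -0.01
    h_true: float = 0.5
    r_bp: float = 1e-12
    focal_freq: float = 0.5


@dataclass(frozen=True)
class GammaDFE:
    """Gamma-distributed |s| of new mutations; selection coefficients are negative."""

    shape: float = 0.186
    scale: float = 0.071

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape and scale must be positive")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return -rng.gamma(self.shape, self.scale, size=n)


def gamma_dfe_mean(dfe: GammaDFE) -> float:
    """Mean selection coefficient of new mutations: -(shape * scale)."""
    return -(dfe.shape * dfe.scale)


@dataclass(frozen=True)
class Epoch:
    duration: int
    n_start: int
    n_end: int | None = None  # exponential change when set, constant otherwise


@dataclass(frozen=True)
class DemographyModel:
    epochs: tuple[Epoch, ...]

    def sizes(self) -> np.ndarray:
        out: list[int] = []
        for ep in self.epochs:
            if ep.n_end is None:
                out.extend([ep.n_start] * ep.duration)
            else:
                g = np.arange(1, ep.duration + 1)
                rate = math.log(ep.n_end / ep.n_start) / ep.duration
                out.extend(np.round(ep.n_start * np.exp(rate * g)).astype(int))
        sizes = np.array(out, dtype=np.int64)
        if np.any(sizes < 2):
            raise ValueError("population size must stay >= 2")
        return sizes

    @classmethod
    def growth(cls, n_constant: int = 10_000, gens_constant: int = 57_000,
               n_final: int = 10_000_000, gens_growth: int = 1_000,
               scale: float = 1.0) -> "DemographyModel":
        """Constant size followed by exponential growth, optionally scaled down."""
        f = max(scale, 1.0)
        return cls((
            Epoch(max(2, int(gens_constant / f)), max(2, int(n_constant / f))),
            Epoch(max(2, int(gens_growth / f)), max(2, int(n_constant / f)),
                  max(2, int(n_final / f))),
        ))


def default_maps(length_bp: int, cm_per_mb_female: float = 1.0,
                 cm_per_mb_male: float = 1.0, chrom: str = "1"):
    fmap = RecombinationMap.uniform("female", chrom, length_bp, cm_per_mb_female)
    mmap = RecombinationMap.uniform("male", chrom, length_bp, cm_per_mb_male)
    return fmap, mmap


# ---------------------------------------------------------------------------
# single-SNP cohorts


def _survival_weights(s: float, h: float, shift: float) -> np.ndarray:
    return np.maximum(0.0, np.array([1.0, 1.0 + h * s, 1.0 + s]) - shift)


def _fix_double_homo(m1, m2, f1, f2, rng, max_rounds: int = 1000):
    """Re-pair fathers until no couple has both parents homozygous for the same allele."""
    n = len(m1)
    order = np.arange(n)
    mg = m1.astype(int) + m2.astype(int)
    for _ in range(max_rounds):
        fg = f1[order].astype(int) + f2[order].astype(int)
        bad = ((mg == 0) & (fg == 0)) | ((mg == 2) & (fg == 2))
        n_bad = int(bad.sum())
        if n_bad == 0:
            return order
        # reshuffle the offending fathers together with an equal number of
        # randomly chosen compliant ones so single offenders can still move
        ok_idx = np.flatnonzero(~bad)
        extra = rng.choice(ok_idx, size=min(len(ok_idx), n_bad), replace=False)
        pool = np.concatenate([np.flatnonzero(bad), extra])
        order[pool] = order[rng.permutation(pool)]
    raise RuntimeError("could not avoid double-homozygous couples; q too extreme")


def gen_single_snp(scenario: SingleSnpScenario, rng: np.random.Generator,
                   n_informative: int | None = None) -> TrioCohort:
    """Cohort at one candidate site: Bernoulli(q) parental haplotypes, one
    child per couple produced by meiosis and a survival trial under
    (s_true, h_true).

    With ``n_informative`` set, generation repeats until that many trios with
    at least one heterozygous parent exist, and exactly those are returned.
    """
    sites = SiteList(np.array(["1"], dtype=object), np.array([10_000]))
    trios: list[Trio] = []
    w = _survival_weights(scenario.s_true, scenario.h_true, scenario.survival_shift)
    if w.max() <= 0:
        raise ValueError("survival weights are all zero under this scenario")
    target = n_informative if n_informative is not None else scenario.n_trios
    batch = scenario.n_trios
    serial = 0

    while len(trios) < target:
        n = batch
        m1, m2, f1, f2 = (rng.random(n) < scenario.q for _ in range(4))
        if scenario.avoid_double_homo:
            order = _fix_double_homo(m1, m2, f1, f2, rng)
            f1, f2 = f1[order], f2[order]

        # one surviving child per couple: repeat Mendelian draws + survival trial
        cm = np.zeros(n, dtype=bool)
        cf = np.zeros(n, dtype=bool)
        pending = np.arange(n)
        while len(pending):
            pick_m = rng.random(len(pending)) < 0.5
            pick_f = rng.random(len(pending)) < 0.5
            tm = np.where(pick_m, m2[pending], m1[pending])
            tf = np.where(pick_f, f2[pending], f1[pending])
            g = tm.astype(int) + tf.astype(int)
            survive = w[g] >= rng.random(len(pending))
            done = pending[survive]
            cm[done] = tm[survive]
            cf[done] = tf[survive]
            pending = pending[~survive]

        for i in range(n):
            if n_informative is not None and (m1[i] == m2[i]) and (f1[i] == f2[i]):
                continue  # uninformative couple
            sid = serial
            serial += 1
            mother = Individual(
                f"m{sid}", "female",
                Haplotype(sites, np.array([m1[i]])), Haplotype(sites, np.array([m2[i]])),
            )
            father = Individual(
                f"d{sid}", "male",
                Haplotype(sites, np.array([f1[i]])), Haplotype(sites, np.array([f2[i]])),
            )
            child = Individual(
                f"c{sid}", "female",
                Haplotype(sites, np.array([cm[i]])), Haplotype(sites, np.array([cf[i]])),
            )
            trios.append(Trio(mother, father, child, 1))
            if len(trios) >= target:
                break
        if n_informative is None:
            break
    return TrioCohort(trios[:target], sites)


# ---------------------------------------------------------------------------
# maximal-LD block cohorts


def _geometric_freq(rng: np.random.Generator) -> float:
    """Truncated-rescaled geometric frequency draw with mean near 0.5.

    k ~ Geometric(1/2) on {1, 2, ...} has mean 2; k/4 has mean 1/2.  Values
    >= 1 are resampled so the result is a valid frequency in (0, 1).
    """
    while True:
        f = rng.geometric(0.5) / 4.0
        if f < 1.0:
            return f


def gen_ld_block(scenario: LDBlockScenario, n_trios: int,
                 rng: np.random.Generator) -> TrioCohort:
    """Cohort with an 11-SNP block in maximal LD (all pairwise D' = 1).

    Haplotypes are built on a single nested genealogy: each haplotype draws
    u ~ U(0, 1) and carries SNP i iff its rank is below freq_i * n_haplotypes,
    so carrier sets are perfectly nested and the focal frequency is exact.
    Viability selection on children uses all SNPs (focal_s at the focal site,
    neighbor_s elsewhere); inference downstream may then restrict to the
    focal SNP.
    """
    ns = scenario.n_snps
    pos = np.arange(ns, dtype=np.int64) * scenario.spacing_bp
    sites = SiteList(np.array(["1"] * ns, dtype=object), pos)
    freqs = np.array([
        scenario.focal_freq if i == scenario.focal_index - 1 else _geometric_freq(rng)
        for i in range(ns)
    ])
    site_s = np.full(ns, scenario.neighbor_s, dtype=np.float64)
    site_s[scenario.focal_index - 1] = scenario.focal_s

    H = 4 * n_trios
    rank = rng.permutation(H)  # haplotype ranks on the single genealogy
    hap = rank[:, None] < np.floor(freqs[None, :] * H)  # (H, ns) nested carriers

    length_bp = int(pos[-1]) + scenario.spacing_bp
    cm_per_mb = scenario.r_bp * 1e8  # Morgans/bp -> cM/Mb
    fmap, mmap = default_maps(length_bp, cm_per_mb, cm_per_mb)

    trios: list[Trio] = []
    for i in range(n_trios):
        mother = Individual(
            f"m{i}", "female",
            Haplotype(sites, hap[4 * i]), Haplotype(sites, hap[4 * i + 1]),
        )
        father = Individual(
            f"d{i}", "male",
            Haplotype(sites, hap[4 * i + 2]), Haplotype(sites, hap[4 * i + 3]),
        )
        child = _survival_child(
            f"c{i}", mother, father, fmap, mmap, site_s, scenario.h_true, 0.0, rng
        )
        trios.append(Trio(mother, father, child, 1))
    return TrioCohort(trios, sites)


# ---------------------------------------------------------------------------
# meiosis + viability helpers (full child haplotypes)


def _gamete_of(parent: Individual, recmap: RecombinationMap,
               rng: np.random.Generator) -> Haplotype:
    sites = parent.hap1.sites
    carriers = np.empty(len(sites), dtype=bool)
    for chrom, sl in sites.chrom_slices().items():
        cx = sample_crossovers(recmap, chrom, rng)
        sub = sites.subset(range(sl.start, sl.stop))
        h1 = Haplotype(sub, parent.hap1.carriers[sl])
        h2 = Haplotype(sub, parent.hap2.carriers[sl])
        start = "A" if rng.random() < 0.5 else "B"
        carriers[sl] = make_gamete(h1, h2, cx, start).carriers
    return Haplotype(sites, carriers)


def _viability(hap_m: Haplotype, hap_p: Haplotype, site_s: np.ndarray,
               h: float, shift: float) -> float:
    homo = hap_m.carriers & hap_p.carriers
    het = hap_m.carriers ^ hap_p.carriers
    f = math.exp(
        np.log1p(site_s[homo]).sum() + np.log1p(h * site_s[het]).sum()
    )
    return max(0.0, f - shift)


def _survival_child(child_id: str, mother: Individual, father: Individual,
                    fmap: RecombinationMap, mmap: RecombinationMap,
                    site_s: np.ndarray, h: float, shift: float,
                    rng: np.random.Generator, max_tries: int = 100_000) -> Individual:
    for _ in range(max_tries):
        gm = _gamete_of(mother, fmap, rng)
        gp = _gamete_of(father, mmap, rng)
        if _viability(gm, gp, site_s, h, shift) >= rng.random():
            return Individual(child_id, "female", gm, gp)
    raise RuntimeError(f"no surviving child for couple ({mother.id}, {father.id})")


# ---------------------------------------------------------------------------
# exome-like parental burden (linkage-equilibrium desk-scale stand-in)


def gen_burden_parents(
    n_parents: int,
    mean_variants_per_parent: float,
    rng: np.random.Generator,
    freq_range: tuple[float, float] = (0.05, 0.5),
    length_bp: int = 50_000_000,
) -> list[Individual]:
    """Parents carrying a target mean number of derived variant sites.

    Per-site derived frequencies are uniform on ``freq_range`` (recessive
    deleterious variants segregate at appreciable frequencies because
    heterozygous carriers are unaffected); haplotypes are drawn independently
    per site (linkage equilibrium), and the number of sites is chosen so the
    expected count of variant sites per parent hits the target.
    """
    lo, hi = freq_range
    # E[1 - (1-q)^2] for q ~ U(lo, hi)
    p_variant = (hi + lo) - (hi**2 + hi * lo + lo**2) / 3.0
    n_sites = max(1, int(round(mean_variants_per_parent / p_variant)))
    q = rng.uniform(lo, hi, size=n_sites)
    pos = np.sort(rng.choice(length_bp, size=n_sites, replace=False))
    sites = SiteList(np.array(["1"] * n_sites, dtype=object), pos.astype(np.int64))
    parents = []
    for i in range(n_parents):
        sex = "female" if i < n_parents // 2 else "male"
        h1 = Haplotype(sites, rng.random(n_sites) < q)
        h2 = Haplotype(sites, rng.random(n_sites) < q)
        parents.append(Individual(f"p{i}", sex, h1, h2))
    return parents


# ---------------------------------------------------------------------------
# Wright-Fisher forward simulator


def forward_wf(
    demography: DemographyModel,
    dfe: GammaDFE | tuple[float, float],
    genome: tuple[int, float, float],
    rng: np.random.Generator,
    scale: float = 1.0,
    dfe_h: float = 0.5,
) -> tuple[SiteList, list[Individual], np.ndarray]:
    """Compact forward Wright-Fisher simulation with multiplicative selection.

    ``genome`` is (target length in bp, mutation rate per site per generation,
    recombination rate per bp per generation).  ``dfe`` is either a GammaDFE
    (per-mutation s drawn from it) or a fixed (s, h) pair.  ``scale`` rescales
    the model (N and durations divided, mu, r, and s multiplied) for desk
    runs.  Selection acts at the mating stage: parents are sampled with
    probability proportional to fitness.  Returns the final generation as
    Individuals plus the per-site selection coefficients.
    """
    L, mu, r_bp = genome
    mu, r_bp = mu * scale, r_bp * scale
    sizes = demography.sizes()
    if scale > 1:
        sizes = np.maximum(2, (sizes / scale).astype(int))[:: max(1, int(scale))]
        if len(sizes) == 0:
            raise ValueError("demography scaled away entirely")
    fixed_sh = None if isinstance(dfe, GammaDFE) else dfe

    positions = np.empty(0, dtype=np.int64)
    site_s = np.empty(0, dtype=np.float64)
    n0 = int(sizes[0])
    haps = np.zeros((2 * n0, 0), dtype=bool)

    for gen_size in sizes:
        n_next = int(gen_size)
        n_cur = haps.shape[0] // 2

        # fitness of current diploids
        if haps.shape[1]:
            A, B = haps[0::2], haps[1::2]
            homo, het = A & B, A ^ B
            if fixed_sh is None:
                logf = homo @ np.log1p(site_s) + het @ np.log1p(dfe_h * site_s)
            else:
                s_fix, h_fix = fixed_sh
                logf = homo.sum(1) * math.log1p(s_fix) + het.sum(1) * math.log1p(
                    h_fix * s_fix
                )
            w = np.exp(logf - logf.max())
        else:
            w = np.ones(n_cur)
        if w.sum() <= 0:
            raise RuntimeError("population extinct: all fitness values are zero")
        p = w / w.sum()

        mothers = rng.choice(n_cur, size=n_next, p=p)
        fathers = rng.choice(n_cur, size=n_next, p=p)
        new_haps = np.zeros((2 * n_next, haps.shape[1]), dtype=bool)
        morgans = r_bp * L
        for j in range(n_next):
            for k, parent in enumerate((mothers[j], fathers[j])):
                h1, h2 = haps[2 * parent], haps[2 * parent + 1]
                ncx = rng.poisson(morgans)
                if ncx and haps.shape[1]:
                    cx = np.sort(rng.integers(0, L, size=ncx))
                    parity = np.searchsorted(cx, positions, side="right") % 2
                    if rng.random() < 0.5:
                        parity = 1 - parity
                    new_haps[2 * j + k] = np.where(parity == 0, h1, h2)
                else:
                    new_haps[2 * j + k] = h1 if rng.random() < 0.5 else h2

        # new mutations (infinite-sites approximation at integer positions)
        n_mut = rng.poisson(2 * n_next * L * mu)
        if n_mut:
            mut_pos = rng.integers(0, L, size=n_mut)
            mut_hap = rng.integers(0, 2 * n_next, size=n_mut)
            add = np.zeros((2 * n_next, n_mut), dtype=bool)
            add[mut_hap, np.arange(n_mut)] = True
            if fixed_sh is None:
                new_s = dfe.draw(n_mut, rng)
            else:
                new_s = np.full(n_mut, fixed_sh[0])
            positions = np.concatenate([positions, mut_pos])
            site_s = np.concatenate([site_s, new_s])
            new_haps = np.concatenate([new_haps, add], axis=1)

        # prune fixed and lost sites
        freq = new_haps.sum(0)
        keep = (freq > 0) & (freq < 2 * n_next)
        haps = new_haps[:, keep]
        positions = positions[keep]
        site_s = site_s[keep]

    order = np.argsort(positions, kind="stable")
    # deduplicate collided positions (rare): offset duplicates by +1 bp
    pos_sorted = positions[order].copy()
    for i in range(1, len(pos_sorted)):
        if pos_sorted[i] <= pos_sorted[i - 1]:
            pos_sorted[i] = pos_sorted[i - 1] + 1
    sites = SiteList(np.array(["1"] * len(pos_sorted), dtype=object), pos_sorted)
    haps = haps[:, order]
    site_s = site_s[order]

    n_final = haps.shape[0] // 2
    individuals = [
        Individual(
            f"p{i}", "female" if i < n_final // 2 else "male",
            Haplotype(sites, haps[2 * i]), Haplotype(sites, haps[2 * i + 1]),
        )
        for i in range(n_final)
    ]
    return sites, individuals, site_s


# ---------------------------------------------------------------------------
# mating + viability selection into a trio cohort


def mate_and_select(
    parents: Sequence[Individual],
    s: float,
    h: float,
    n_children_target: int,
    rng: np.random.Generator,
    embryos_per_couple: int = 10,
    site_s: np.ndarray | None = None,
    female_map: RecombinationMap | None = None,
    male_map: RecombinationMap | None = None,
    survival_shift: float = 0.0,
) -> TrioCohort:
    """Random mating, viability selection on embryos, down-sampling to target.

    Each couple produces ``embryos_per_couple`` embryos; an embryo survives
    iff its fitness (minus any shift) is at least a uniform(0, 1) draw.
    Survivors are down-sampled at random to ``n_children_target``, so sibling
    structure is retained.  ``site_s`` overrides the scalar s per site (DFE
    cohorts or shifted-s scenarios use this).
    """
    females = [p for p in parents if p.sex == "female"]
    males = [p for p in parents if p.sex == "male"]
    if not females or not males:
        raise ValueError("need parents of both sexes")
    n_couples = min(len(females), len(males))
    females = [females[i] for i in rng.permutation(len(females))[:n_couples]]
    males = [males[i] for i in rng.permutation(len(males))[:n_couples]]

    sites = females[0].hap1.sites
    if site_s is None:
        site_s = np.full(len(sites), s, dtype=np.float64)
    if female_map is None or male_map is None:
        length = int(sites.pos.max()) + 1 if len(sites) else 1
        fmap, mmap = default_maps(length, 1.0, 1.0, chrom=str(sites.chrom[0]))
        female_map = female_map or fmap
        male_map = male_map or mmap

    from .meiosis import _gamete_alleles_block

    chrom_slices = sites.chrom_slices()
    # survivors kept sparse: (couple, union site indices, maternal/paternal bits)
    survivors: list[tuple[int, np.ndarray, np.ndarray, np.ndarray]] = []
    for c in range(n_couples):
        mother, father = females[c], males[c]
        union = np.flatnonzero(mother.carries() | father.carries())
        if len(union) == 0:
            M = P = np.zeros((embryos_per_couple, 0), dtype=bool)
            f = np.ones(embryos_per_couple)
        else:
            m_blocks, p_blocks = [], []
            for chrom, sl in chrom_slices.items():
                in_chrom = union[(union >= sl.start) & (union < sl.stop)]
                if len(in_chrom) == 0:
                    continue
                pos = sites.pos[in_chrom].astype(np.float64)
                m_blocks.append(_gamete_alleles_block(
                    mother.hap1.carriers[in_chrom], mother.hap2.carriers[in_chrom],
                    pos, female_map, chrom, embryos_per_couple, rng))
                p_blocks.append(_gamete_alleles_block(
                    father.hap1.carriers[in_chrom], father.hap2.carriers[in_chrom],
                    pos, male_map, chrom, embryos_per_couple, rng))
            M = np.concatenate(m_blocks, axis=1)
            P = np.concatenate(p_blocks, axis=1)
            ls = np.log1p(site_s[union])
            lhs = np.log1p(h * site_s[union])
            f = np.exp((M & P) @ ls + (M ^ P) @ lhs) - survival_shift
        alive = f >= rng.random(embryos_per_couple)
        for j in np.flatnonzero(alive):
            survivors.append((c, union, M[j], P[j]))

    if len(survivors) < n_children_target:
        raise ValueError(
            f"only {len(survivors)} embryos survived selection "
            f"(target {n_children_target}); provide more parents"
        )
    picked = rng.choice(len(survivors), size=n_children_target, replace=False)
    chosen = [survivors[i] for i in sorted(picked)]

    n_children: dict[int, int] = {}
    for c, _, _, _ in chosen:
        n_children[c] = n_children.get(c, 0) + 1
    trios = []
    for j, (c, union, mbits, pbits) in enumerate(chosen):
        hm = np.zeros(len(sites), dtype=bool)
        hp = np.zeros(len(sites), dtype=bool)
        hm[union] = mbits
        hp[union] = pbits
        child = Individual(
            f"c{j}", "female", Haplotype(sites, hm), Haplotype(sites, hp)
        )
        trios.append(Trio(females[c], males[c], child, n_children[c]))
    return TrioCohort(trios, sites)


# ---------------------------------------------------------------------------
# recovery benchmark harness


def recovery_report(
    scenario: SingleSnpScenario,
    n_replicates: int,
    prior,
    config,
    rng: np.random.Generator,
    n_informative: int | None = None,
    opts=None,
) -> pd.DataFrame:
    """Replicate generation + inference; tabulate posterior medians, CIs,
    coverage flags, and the n*|s| inferential-power diagnostic."""
    from .abc import infer  # local import to avoid a cycle

    rows = []
    for rep in range(n_replicates):
        cohort = gen_single_snp(scenario, rng, n_informative=n_informative)
        fmap, mmap = default_maps(1_000_000)
        cfg = type(config)(**{**config.__dict__, "seed": int(rng.integers(2**31))})
        post, diag = infer(cohort, fmap, mmap, prior, cfg, opts=opts)
        s_lo, s_hi = post.credible_interval("s")
        h_lo, h_hi = post.credible_interval("h")
        n_used = diag["n_trios_used"]
        rows.append({
            "replicate": rep,
            "s_true": scenario.s_true,
            "h_true": scenario.h_true,
            "n_trios": n_used,
            "ns_product": n_used * abs(scenario.s_true),
            "s_median": post.median("s"),
            "s_lo": s_lo,
            "s_hi": s_hi,
            "s_covered": s_lo <= scenario.s_true <= s_hi,
            "h_median": post.median("h"),
            "h_lo": h_lo,
            "h_hi": h_hi,
            "h_covered": h_lo <= scenario.h_true <= h_hi,
        })
        if rows[-1]["ns_product"] < 100:
            logger.warning(
                "replicate %d: n*|s| = %.3g is small; expect wide intervals",
                rep, rows[-1]["ns_product"],
            )
    return pd.DataFrame(rows)
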