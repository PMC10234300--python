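"""Two-stage ABC: pilot run, empirical prior update, final run, adjustment.

The inference loop is: (1) simulate a pilot reference table under broad
priors, (2) accept the closest proportion ``t`` of simulations by Euclidean
distance between observed and simulated summary statistics, (3) turn the
sorted accepted parameter values into empirical priors, (4) simulate a final
reference table under those priors, and (5) apply rejection followed by
local-linear regression adjustment to paint the posterior.  Model choice
pools equal-sized reference tables from constrained models and reads
posterior probabilities off the acceptance rates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._kernels import sim_counts, sim_single_site
from .datatypes import SelectionParams, TrioCohort
from .meiosis import DeNovoConfig, ZygoteArrays, build_zygote_arrays, strip_de_novo
from .recomb import RecombinationMap
from .selection import FitnessOptions
from .summaries import (
    MeanCounts,
    SummaryVector,
    mean_counts,
    observed_summary,
    offspring_means,
    parental_means,
    summary_vector,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PriorSpec",
    "ABCConfig",
    "ReferenceTable",
    "EmpiricalPrior",
    "Posterior",
    "ModelPosterior",
    "sample_prior",
    "run_reference",
    "rejection",
    "empirical_draw",
    "regression_adjust",
    "model_select",
    "informative_trios",
    "infer",
    "model_selection",
]

Model = Literal["free", "neutral", "recessive", "additive"]
CONSTRAINED_H = {"recessive": 0.0, "additive": 0.5}


@dataclass(frozen=True)
class PriorSpec:
    """Priors on h (uniform) and s (log-uniform over |s|, or uniform).

    For the log-uniform case ``s_range`` holds magnitudes (lo, hi) and
    ``s_sign`` fixes the sign (negative for deleterious candidates); for the
    uniform case ``s_range`` is the raw open interval and the sign is unused.
    """

    h_range: tuple[float, float] = (-0.1, 0.6)
    s_dist: Literal["log_uniform", "uniform"] = "log_uniform"
    s_range: tuple[float, float] = (1e-5, 1e-1)
    s_sign: int = -1

    def __post_init__(self) -> None:
        if not self.h_range[0] < self.h_range[1]:
            raise ValueError("empty h prior interval")
        if not self.s_range[0] < self.s_range[1]:
            raise ValueError("empty s prior interval")
        if self.s_dist == "log_uniform":
            if self.s_range[0] <= 0:
                raise ValueError("log-uniform magnitudes must be positive")
            if self.s_sign not in (-1, 1):
                raise ValueError("s_sign must be -1 or +1")
        # the support is an open interval, so boundary equality is allowed
        lo, hi = self.s_support()
        for s in (lo, hi):
            for h in self.h_range:
                if 1.0 + s < 0.0 or 1.0 + h * s < 0.0:
                    raise ValueError(
                        "prior support violates fitness validity (1+s>0, 1+h*s>0)"
                    )

    def s_support(self) -> tuple[float, float]:
        """Raw (min, max) interval of s under this prior."""
        lo, hi = self.s_range
        if self.s_dist == "uniform":
            return lo, hi
        return (-hi, -lo) if self.s_sign < 0 else (lo, hi)

    def sample_s(self, rng: np.random.Generator) -> float:
        lo, hi = self.s_range
        if self.s_dist == "uniform":
            return float(rng.uniform(lo, hi))
        mag = 10.0 ** rng.uniform(math.log10(lo), math.log10(hi))
        return float(self.s_sign * mag)

    def sample_h(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(*self.h_range))


def sample_prior(spec: PriorSpec, rng: np.random.Generator) -> SelectionParams:
    return SelectionParams(spec.sample_s(rng), spec.sample_h(rng))


@dataclass(frozen=True)
class ABCConfig:
    m_pilot: int = 50_000
    m_final: int = 50_000
    t: float = 0.01
    t_final: float = 0.01
    standardize: bool = True
    seed: int | None = None
    zygotes_per_trio: int = 150

    def __post_init__(self) -> None:
        if not (0 < self.t <= 1 and 0 < self.t_final <= 1):
            raise ValueError("acceptance proportions must be in (0, 1]")
        if self.m_pilot < 1 or self.m_final < 1:
            raise ValueError("simulation counts must be >= 1")


@dataclass
class ReferenceTable:
    """Rows of (model, s, h, delta_homo, delta_het) plus a failure count."""

    df: pd.DataFrame
    n_failures: int = 0

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_requested(self) -> int:
        return len(self.df) + self.n_failures


class EmpiricalPrior:
    """Sorted array of accepted parameter values used as an updated prior."""

    def __init__(self, values: Sequence[float]) -> None:
        arr = np.sort(np.asarray(values, dtype=np.float64))
        if len(arr) < 2:
            raise ValueError("empirical prior needs at least 2 values")
        self.values = arr

    def draw(self, rng: np.random.Generator) -> float:
        return empirical_draw(self, rng)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])


def empirical_draw(prior: EmpiricalPrior, rng: np.random.Generator) -> float:
    """Resample from a sorted array of accepted values.

    Pick one element uniformly at random; form an interval with its
    neighbour(s) (next element if it is the first, previous if the last,
    otherwise the previous and next elements); return a uniform draw on that
    interval.
    """
    v = prior.values
    i = int(rng.integers(len(v)))
    if i == 0:
        lo, hi = v[0], v[1]
    elif i == len(v) - 1:
        lo, hi = v[-2], v[-1]
    else:
        lo, hi = v[i - 1], v[i + 1]
    return float(rng.uniform(lo, hi))


@dataclass
class Posterior:
    """Accepted (and optionally regression-adjusted) parameter samples."""

    samples: pd.DataFrame  # columns: s, h, distance
    adjusted: pd.DataFrame | None = None
    q_obs: SummaryVector | None = None

    def values(self, param: str, adjusted: bool = True) -> np.ndarray:
        src = self.adjusted if adjusted and self.adjusted is not None else self.samples
        return src[param].to_numpy()

    def median(self, param: str, adjusted: bool = True) -> float:
        return float(np.median(self.values(param, adjusted)))

    def credible_interval(
        self, param: str, level: float = 0.95, adjusted: bool = True
    ) -> tuple[float, float]:
        v = self.values(param, adjusted)
        alpha = (1.0 - level) / 2.0
        return float(np.quantile(v, alpha)), float(np.quantile(v, 1.0 - alpha))


@dataclass
class ModelPosterior:
    """Posterior model probabilities from pooled-acceptance model choice."""

    probs: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.probs.values())
        if total <= 0:
            raise ValueError("model probabilities must have positive mass")
        self.probs = {k: v / total for k, v in self.probs.items()}

    def __getitem__(self, model: str) -> float:
        return self.probs[model]

    def best(self) -> str:
        return max(self.probs, key=self.probs.get)


def _genotype_class_counts(arrays: ZygoteArrays) -> np.ndarray:
    """(n_couples, 3) counts of zygotes with 0/1/2 derived copies (single-SNP)."""
    cached = getattr(arrays, "_g3_cache", None)
    if cached is not None:
        return cached
    g = 2 * arrays.KH + arrays.KT
    G = np.stack([(g == k).sum(axis=1) for k in range(3)], axis=1).astype(np.float64)
    arrays._g3_cache = G
    return G


def _draw_params(
    priors, model: Model, rng: np.random.Generator
) -> tuple[float, float]:
    if isinstance(priors, PriorSpec):
        s, h = priors.sample_s(rng), priors.sample_h(rng)
    else:
        s_prior, h_prior = priors
        s, h = s_prior.draw(rng), h_prior.draw(rng)
    if model == "neutral":
        s = 0.0
    elif model in CONSTRAINED_H:
        h = CONSTRAINED_H[model]
    return s, h


def run_reference(
    arrays: ZygoteArrays,
    priors,
    m: int,
    model: Model = "free",
    opts: FitnessOptions | None = None,
    parent_means: MeanCounts | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> ReferenceTable:
    """Simulate m ABC iterations over prebuilt zygote arrays.

    ``priors`` is either a PriorSpec or an (EmpiricalPrior_s, EmpiricalPrior_h)
    pair.  Constrained models fix h (recessive 0, additive 0.5) or s (neutral
    0) after drawing, so the same random substreams produce aligned draws
    across models.  Lethal parameter draws (a couple whose zygotes all have
    zero fitness) are recorded as failures and contribute no row.
    """
    if parent_means is None:
        raise ValueError("run_reference requires parental means (x0, y0)")
    opts = opts or FitnessOptions()
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    # explicit spawn keys: repeated calls with the same SeedSequence reuse the
    # same per-row substreams (constrained models share randomness)
    row_seeds = [
        np.random.SeedSequence(entropy=seed.entropy, spawn_key=seed.spawn_key + (i,))
        for i in range(m)
    ]

    n_children = arrays.n_children
    total_children = arrays.total_children
    shift, floor = opts.shift, opts.floor
    single = arrays.single_site
    G = _genotype_class_counts(arrays) if single else None
    KH = arrays.KH.astype(np.float64) if not single else None
    KT = arrays.KT.astype(np.float64) if not single else None

    out_s = np.empty(m)
    out_h = np.empty(m)
    out_dh = np.empty(m)
    out_dt = np.empty(m)
    kept = 0
    failures = 0
    for i in range(m):
        rng = np.random.default_rng(row_seeds[i])
        s, h = _draw_params(priors, model, rng)
        u = rng.uniform(size=total_children)
        if single:
            w1 = max(floor, 1.0 - shift)
            w2 = max(floor, 1.0 + h * s - shift)
            w3 = max(floor, 1.0 + s - shift)
            sh, st, fail = sim_single_site(G, n_children, w1, w2, w3, u)
        else:
            sh, st, fail = sim_counts(
                KH, KT, n_children, math.log1p(s), math.log1p(h * s), shift, floor, u
            )
        if fail >= 0:
            failures += 1
            logger.warning(
                "lethal draw (s=%g, h=%g) for couple %s; iteration rejected",
                s, h, arrays.couple_ids[fail],
            )
            continue
        out_s[kept] = s
        out_h[kept] = h
        out_dh[kept] = sh / total_children - parent_means.mean_homo
        out_dt[kept] = st / total_children - parent_means.mean_het
        kept += 1

    df = pd.DataFrame(
        {
            "model": model,
            "s": out_s[:kept],
            "h": out_h[:kept],
            "delta_homo": out_dh[:kept],
            "delta_het": out_dt[:kept],
        }
    )
    return ReferenceTable(df, n_failures=failures)


def _distances(
    df: pd.DataFrame, q_obs: SummaryVector, standardize: bool
) -> np.ndarray:
    S = df[["delta_homo", "delta_het"]].to_numpy(dtype=np.float64)
    resid = S - q_obs.as_array()[None, :]
    if standardize:
        sigma = stats.median_abs_deviation(S, axis=0)
        sigma = np.where(sigma > 0, sigma, 1.0)
        resid = resid / sigma[None, :]
    return np.sqrt((resid**2).sum(axis=1))


def rejection(
    table: ReferenceTable | pd.DataFrame,
    q_obs: SummaryVector,
    t: float,
    standardize: bool = True,
) -> Posterior:
    """Accept the proportion t of simulations closest to the observed summaries.

    Distance is Euclidean over (delta_homo, delta_het), optionally scaled per
    statistic by its median absolute deviation across the table.  Ties are
    broken by row order.
    """
    df = table.df if isinstance(table, ReferenceTable) else table
    if len(df) == 0:
        raise ValueError("empty reference table")
    if t * len(df) < 1:
        raise ValueError(f"t={t} accepts no rows out of {len(df)}")
    d = _distances(df, q_obs, standardize)
    n_accept = math.ceil(t * len(df))
    order = np.argsort(d, kind="stable")[:n_accept]
    accepted = df.iloc[order][["s", "h"]].copy()
    accepted["distance"] = d[order]
    return Posterior(accepted.reset_index(drop=True), q_obs=q_obs)


def _adjust_one(
    theta: np.ndarray, X: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Weighted local-linear adjustment of one parameter; returns (values, ok)."""
    A = np.column_stack([np.ones(len(X)), X])
    sw = np.sqrt(w)
    beta, _, rank, _ = np.linalg.lstsq(A * sw[:, None], theta * sw, rcond=None)
    if rank < A.shape[1]:
        return theta, False
    return theta - X @ beta[1:], True


def regression_adjust(
    posterior: Posterior,
    q_obs: SummaryVector,
    prior: PriorSpec | None = None,
) -> Posterior:
    """Local-linear regression adjustment with Epanechnikov distance weights.

    s is adjusted on the log10|s| scale when the prior is log-uniform (so the
    correction respects the prior geometry); h is adjusted untransformed.
    Adjusted values are clamped to the prior support.  Degenerate designs
    (constant summaries or zero distance spread) fall back to the unadjusted
    rejection sample with a warning.
    """
    acc = posterior.samples
    if len(acc) < 2:
        raise ValueError("regression adjustment needs at least 2 accepted rows")
    if len(acc) < 10:
        logger.warning("fewer than 10 accepted rows; skipping adjustment")
        posterior.adjusted = acc[["s", "h"]].copy()
        return posterior

    # rejection stores only (s, h, distance); the accepted rows' summary
    # coordinates are attached as `_summaries` by the rejection-with-summaries
    # path used in infer()
    X = getattr(posterior, "_summaries", None)
    if X is None:
        raise ValueError(
            "posterior lacks attached summaries; use infer() or attach _summaries"
        )
    X = X - q_obs.as_array()[None, :]

    d = acc["distance"].to_numpy()
    dmax = d.max()
    if dmax <= 0 or np.allclose(X.std(axis=0), 0):
        logger.warning("degenerate design; returning unadjusted sample")
        posterior.adjusted = acc[["s", "h"]].copy()
        return posterior
    w = 1.0 - (d / dmax) ** 2
    if w.sum() <= 0:
        w = np.ones_like(w)

    s = acc["s"].to_numpy().copy()
    h = acc["h"].to_numpy().copy()
    log_scale = prior is not None and prior.s_dist == "log_uniform"
    if log_scale and np.all(s != 0):
        theta_s = np.log10(np.abs(s))
        adj, ok = _adjust_one(theta_s, X, w)
        if ok:
            s = np.sign(s) * 10.0**adj
    else:
        adj, ok = _adjust_one(s, X, w)
        if ok:
            s = adj
    h_adj, ok_h = _adjust_one(h, X, w)
    if ok_h:
        h = h_adj
    if not (ok and ok_h):
        logger.warning("singular design in regression adjustment; partial fallback")

    if prior is not None:
        s_lo, s_hi = prior.s_support()
        s = np.clip(s, s_lo, s_hi)
        h = np.clip(h, *prior.h_range)
    posterior.adjusted = pd.DataFrame({"s": s, "h": h})
    return posterior


def _rejection_with_summaries(
    table: ReferenceTable, q_obs: SummaryVector, t: float, standardize: bool
) -> Posterior:
    df = table.df
    post = rejection(table, q_obs, t, standardize)
    d = _distances(df, q_obs, standardize)
    order = np.argsort(d, kind="stable")[: len(post.samples)]
    post._summaries = df.iloc[order][["delta_homo", "delta_het"]].to_numpy(
        dtype=np.float64
    )
    return post


def model_select(
    tables: dict[str, ReferenceTable],
    q_obs: SummaryVector,
    t: float,
    standardize: bool = True,
) -> ModelPosterior:
    """Posterior model probabilities via pooled rejection acceptance rates.

    Requires the same number of simulations per model (equal prior model
    probabilities).  All rows are pooled, ranked by distance, and the top
    proportion t accepted; each model's probability is its share of the
    accepted rows.
    """
    counts = {name: tab.n_requested for name, tab in tables.items()}
    if len(set(counts.values())) != 1:
        raise ValueError(f"unequal simulation counts per model: {counts}")
    pooled = pd.concat([tab.df for tab in tables.values()], ignore_index=True)
    post = rejection(ReferenceTable(pooled), q_obs, t, standardize)
    d = _distances(pooled, q_obs, standardize)
    order = np.argsort(d, kind="stable")[: len(post.samples)]
    labels = pooled["model"].to_numpy()[order]
    probs = {name: float((labels == name).mean()) for name in tables}
    return ModelPosterior(probs)


def informative_trios(cohort: TrioCohort) -> TrioCohort:
    """Single-SNP filter: keep trios where at least one parent is heterozygous."""
    if len(cohort.candidate_sites) != 1:
        raise ValueError("informative-trio filter applies to single-SNP cohorts")
    kept = [
        t for t in cohort.trios if t.mother.is_het(0) or t.father.is_het(0)
    ]
    return TrioCohort(kept, cohort.candidate_sites)


def _strip_cohort(cohort: TrioCohort) -> TrioCohort:
    trios = [
        type(t)(t.mother, t.father, strip_de_novo(t.child, t.mother, t.father),
                t.n_children_of_couple)
        for t in cohort.trios
    ]
    return TrioCohort(trios, cohort.candidate_sites)


def infer(
    cohort: TrioCohort,
    female_map: RecombinationMap,
    male_map: RecombinationMap,
    prior: PriorSpec,
    config: ABCConfig,
    opts: FitnessOptions | None = None,
    denovo: DeNovoConfig | None = None,
) -> tuple[Posterior, dict]:
    """End-to-end two-stage ABC inference of (s, h) on a trio cohort."""
    opts = opts or FitnessOptions()
    diagnostics: dict = {"n_trios_input": cohort.n}

    if len(cohort.candidate_sites) == 1:
        cohort = informative_trios(cohort)
        if cohort.n == 0:
            raise ValueError(
                "no informative trios: single-SNP inference requires trios where "
                "at least one parent is heterozygous at the focal site"
            )
    diagnostics["n_trios_used"] = cohort.n

    if denovo is None or denovo.rate == 0:
        obs_cohort = _strip_cohort(cohort)
    else:
        obs_cohort = cohort
    x0y0 = parental_means(obs_cohort)
    q_obs = summary_vector(offspring_means(obs_cohort), x0y0)
    diagnostics["q_obs"] = (q_obs.delta_homo, q_obs.delta_het)

    root = np.random.SeedSequence(config.seed)
    ss_arrays, ss_pilot, ss_final = root.spawn(3)
    arrays = build_zygote_arrays(
        cohort, female_map, male_map, config.zygotes_per_trio, denovo,
        seed=int(ss_arrays.generate_state(1)[0]),
    )

    pilot = run_reference(
        arrays, prior, config.m_pilot, "free", opts, x0y0, ss_pilot
    )
    diagnostics["pilot_failures"] = pilot.n_failures
    pilot_post = rejection(pilot, q_obs, config.t, config.standardize)
    if len(pilot_post.samples) < 2:
        raise ValueError(
            "fewer than 2 accepted pilot simulations; increase m_pilot or t"
        )
    s_prior = EmpiricalPrior(pilot_post.samples["s"])
    h_prior = EmpiricalPrior(pilot_post.samples["h"])
    diagnostics["pilot_accepted"] = len(pilot_post.samples)

    final = run_reference(
        arrays, (s_prior, h_prior), config.m_final, "free", opts, x0y0, ss_final
    )
    diagnostics["final_failures"] = final.n_failures
    post = _rejection_with_summaries(final, q_obs, config.t_final, config.standardize)
    post = regression_adjust(post, q_obs, prior)
    diagnostics["final_accepted"] = len(post.samples)
    return post, diagnostics


def model_selection(
    cohort: TrioCohort,
    female_map: RecombinationMap,
    male_map: RecombinationMap,
    prior: PriorSpec,
    config: ABCConfig,
    models: Sequence[str] = ("neutral", "recessive", "additive"),
    opts: FitnessOptions | None = None,
    denovo: DeNovoConfig | None = None,
) -> tuple[ModelPosterior, dict]:
    """Fit constrained models with equal simulation counts and compare them."""
    opts = opts or FitnessOptions()
    diagnostics: dict = {}
    if denovo is None or denovo.rate == 0:
        obs_cohort = _strip_cohort(cohort)
    else:
        obs_cohort = cohort
    x0y0 = parental_means(obs_cohort)
    q_obs = summary_vector(offspring_means(obs_cohort), x0y0)
    diagnostics["q_obs"] = (q_obs.delta_homo, q_obs.delta_het)

    root = np.random.SeedSequence(config.seed)
    ss_arrays, ss_run = root.spawn(2)
    arrays = build_zygote_arrays(
        cohort, female_map, male_map, config.zygotes_per_trio, denovo,
        seed=int(ss_arrays.generate_state(1)[0]),
    )
    tables = {
        model: run_reference(
            arrays, prior, config.m_final, model, opts, x0y0, ss_run
        )
        for model in models
    }
    diagnostics["failures"] = {m: t.n_failures for m, t in tables.items()}
    return model_select(tables, q_obs, config.t, config.standardize), diagnostics
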