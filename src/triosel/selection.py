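"""Fitness computation and viability selection over zygote arrays.

Fitness is multiplicative over candidate sites:

    f = (1 + s)^k_homo * (1 + h*s)^k_het

In beneficial mode a constant (default 0.2) is subtracted from every fitness
value so survival probabilities stay below one; the result is floored at
zero.  Sampling one zygote per child with probability proportional to
fitness is distributionally identical to repeatedly drawing a random zygote
and keeping it with probability equal to its fitness until one survives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .datatypes import GenotypeCounts, SelectionParams
from .meiosis import Zygote, ZygoteArray, ZygoteArrays

__all__ = [
    "FitnessOptions",
    "LethalCoupleError",
    "fitness",
    "zygote_weights",
    "select_zygote",
    "select_cohort",
]

_LOG_SCALE_THRESHOLD = 1000  # counts above this are computed on log scale


@dataclass(frozen=True)
class FitnessOptions:
    mode: Literal["deleterious", "beneficial"] = "deleterious"
    beneficial_shift: float = 0.2
    floor: float = 0.0

    def __post_init__(self) -> None:
        if self.floor < 0:
            raise ValueError("fitness floor must be >= 0")

    @property
    def shift(self) -> float:
        return self.beneficial_shift if self.mode == "beneficial" else 0.0


class LethalCoupleError(RuntimeError):
    """All zygotes of a couple have zero fitness under the proposed parameters."""

    def __init__(self, couple_id) -> None:
        super().__init__(
            f"all zygotes of couple {couple_id} have zero fitness; "
            "parameter combination is lethal for this couple"
        )
        self.couple_id = couple_id


def fitness(
    counts: GenotypeCounts,
    params: SelectionParams,
    opts: FitnessOptions | None = None,
) -> float:
    kh, kt = counts.k_homo, counts.k_het
    if kh + kt > _LOG_SCALE_THRESHOLD:
        f = math.exp(kh * math.log1p(params.s) + kt * math.log1p(params.h * params.s))
    else:
        f = (1.0 + params.s) ** kh * (1.0 + params.h * params.s) ** kt
    if opts is not None and opts.shift:
        f = max(opts.floor, f - opts.shift)
    return f


def zygote_weights(
    array: ZygoteArray,
    params: SelectionParams,
    opts: FitnessOptions | None = None,
) -> np.ndarray:
    """Per-zygote selection weights (fitness, after any beneficial shift)."""
    lw1 = math.log1p(params.s)
    lw2 = math.log1p(params.h * params.s)
    w = np.exp(array.k_homo * lw1 + array.k_het * lw2)
    if opts is not None and opts.shift:
        w = np.maximum(opts.floor, w - opts.shift)
    return w


def select_zygote(
    array: ZygoteArray,
    params: SelectionParams,
    opts: FitnessOptions | None,
    rng: np.random.Generator,
) -> Zygote:
    """Draw one zygote with probability proportional to its fitness."""
    w = zygote_weights(array, params, opts)
    tot = w.sum()
    if tot <= 0:
        raise LethalCoupleError(array.couple_id)
    j = int(np.searchsorted(np.cumsum(w), rng.uniform(0, tot), side="left"))
    return array.zygote(min(j, len(array) - 1))


def select_cohort(
    arrays: ZygoteArrays | Sequence[ZygoteArray],
    params: SelectionParams,
    opts: FitnessOptions | None,
    rng: np.random.Generator,
) -> list[Zygote]:
    """One fitness-proportional draw per observed child, in couple order."""
    out: list[Zygote] = []
    for array in arrays:
        for _ in range(array.n_children):
            out.append(select_zygote(array, params, opts, rng))
    return out
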