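"""Sex-specific recombination maps (bp -> cumulative centimorgan)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = ["RecombinationMap"]


@dataclass
class RecombinationMap:
    """Piecewise-linear genetic map per chromosome.

    Cumulative cM is non-decreasing in bp.  Queries outside the breakpoint
    range are clamped to the first/last cM value (constant extrapolation).
    """

    sex: Literal["female", "male"]
    chrom_maps: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def add_chromosome(self, chrom: str, pos_bp: np.ndarray, cum_cm: np.ndarray) -> None:
        pos_bp = np.asarray(pos_bp, dtype=np.float64)
        cum_cm = np.asarray(cum_cm, dtype=np.float64)
        if pos_bp.shape != cum_cm.shape or pos_bp.ndim != 1 or len(pos_bp) < 2:
            raise ValueError("map needs >= 2 (pos, cM) breakpoints per chromosome")
        if np.any(np.diff(pos_bp) <= 0):
            raise ValueError(f"breakpoint positions must increase on {chrom}")
        if np.any(np.diff(cum_cm) < 0):
            raise ValueError(f"cumulative cM decreases on {chrom}")
        self.chrom_maps[chrom] = (pos_bp, cum_cm)

    @classmethod
    def uniform(
        cls,
        sex: Literal["female", "male"],
        chrom: str,
        length_bp: int,
        cm_per_mb: float,
    ) -> "RecombinationMap":
        m = cls(sex=sex)
        total_cm = cm_per_mb * length_bp / 1e6
        m.add_chromosome(chrom, np.array([0.0, float(length_bp)]), np.array([0.0, total_cm]))
        return m

    def _get(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        try:
            return self.chrom_maps[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not present in {self.sex} map") from None

    def cm_at(self, chrom: str, pos) -> np.ndarray:
        pos_bp, cum_cm = self._get(chrom)
        return np.interp(np.asarray(pos, dtype=np.float64), pos_bp, cum_cm)

    def distance_cm(self, chrom: str, a: float, b: float) -> float:
        """Genetic distance in cM between two bp positions."""
        lo, hi = self.cm_at(chrom, [a, b])
        return abs(float(hi) - float(lo))

    def total_cm(self, chrom: str) -> float:
        _, cum_cm = self._get(chrom)
        return float(cum_cm[-1] - cum_cm[0])

    def chromosomes(self) -> list[str]:
        return list(self.chrom_maps)

    def sample_positions(self, chrom: str, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n bp positions with density proportional to local cM/bp.

        Inverse-CDF on the cumulative map: uniform draws on [cM_first, cM_last]
        mapped back through the piecewise-linear map.
        """
        pos_bp, cum_cm = self._get(chrom)
        u = rng.uniform(cum_cm[0], cum_cm[-1], size=n)
        return np.interp(u, cum_cm, pos_bp)
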