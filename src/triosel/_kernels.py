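"""Numba inner loops for fitness-proportional zygote sampling.

These kernels implement one ABC iteration over the whole cohort: compute
zygote fitnesses, draw one zygote per observed child with probability
proportional to fitness, and accumulate the sums of k_homo and k_het of the
survivors.  A negative third return value means success; otherwise it is the
index of a couple whose zygotes all had zero fitness (lethal parameter draw).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["sim_counts", "sim_single_site"]


@njit(cache=True)
def sim_counts(KH, KT, n_children, log_w_homo, log_w_het, shift, floor, u):
    """General path: per-zygote fitness exp(k_homo*log(1+s) + k_het*log(1+h*s))."""
    C, Z = KH.shape
    w = np.empty(Z, dtype=np.float64)
    sum_homo = 0.0
    sum_het = 0.0
    ui = 0
    for c in range(C):
        tot = 0.0
        for z in range(Z):
            f = np.exp(KH[c, z] * log_w_homo + KT[c, z] * log_w_het) - shift
            if f < floor:
                f = floor
            w[z] = f
            tot += f
        if tot <= 0.0:
            return np.nan, np.nan, c
        for _ in range(n_children[c]):
            r = u[ui] * tot
            ui += 1
            acc = 0.0
            pick = Z - 1
            for z in range(Z):
                acc += w[z]
                if acc >= r:
                    pick = z
                    break
            sum_homo += KH[c, pick]
            sum_het += KT[c, pick]
    return sum_homo, sum_het, -1


@njit(cache=True)
def sim_single_site(G, n_children, w0, w1, w2, u):
    """Single-SNP path: zygotes grouped by genotype.

    G is an (n_couples, 3) matrix counting zygotes with 0/1/2 derived copies;
    sampling a genotype class with probability proportional to count * fitness
    is distributionally identical to sampling individual zygotes.
    """
    C = G.shape[0]
    sum_homo = 0.0
    sum_het = 0.0
    ui = 0
    for c in range(C):
        t0 = G[c, 0] * w0
        t1 = G[c, 1] * w1
        t2 = G[c, 2] * w2
        tot = t0 + t1 + t2
        if tot <= 0.0:
            return np.nan, np.nan, c
        for _ in range(n_children[c]):
            r = u[ui] * tot
            ui += 1
            if r <= t0:
                pass
            elif r <= t0 + t1:
                sum_het += 1.0
            else:
                sum_homo += 1.0
    return sum_homo, sum_het, -1
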