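"""Independent forward-in-time Wright-Fisher oracle for the coalescent tests.

This simulator shares nothing with the package's backward-in-time machinery:
it evolves an explicit population of haplotypes forward through time. Each
generation, every child haplotype is built by recombining a "locus parent"
(which contributes the segment containing the mutator locus) with a random
partner haplotype, and receives new mutations at a rate set by the model's
meiosis convention: phi*mu per bp for carrier children, and
mu*(1 + (phi-1)*f) per bp for non-carrier children (a non-carrier chromosome
is transmitted by a parent who also carries a mutator chromosome with
probability f, and then mutates at the elevated rate).

The mutator-allele frequency is held at a fixed value f each generation
(the zero-selection deterministic trajectory), by drawing exactly
round(2N*f) children whose locus parent is a carrier. The population starts
monomorphic; neutral background diversity therefore contributes zero
expected *difference* between carrier and non-carrier derived counts, which
is the statistic this oracle is used to cross-check.
"""

from __future__ import annotations

import numpy as np


def _recombine(
    a: np.ndarray, b: np.ndarray, locus: float, breaks: np.ndarray
) -> np.ndarray:
    """Mosaic of two sorted position arrays; the segment containing ``locus``
    comes from ``a`` and ancestry alternates at each breakpoint."""
    if breaks.size == 0:
        return a.copy()
    locus_par = np.searchsorted(breaks, locus)
    par_a = np.searchsorted(breaks, a)
    par_b = np.searchsorted(breaks, b)
    take_a = a[(par_a - locus_par) % 2 == 0]
    take_b = b[(par_b - locus_par) % 2 == 1]
    return np.sort(np.concatenate([take_a, take_b]))


def forward_population(
    N: int,
    L: float,
    locus: float,
    mu: float,
    rho: float,
    phi: float,
    f: float,
    g: int,
    seed: int,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Run the forward simulation; returns (haplotypes, carrier flags).

    Haplotypes are sorted arrays of mutation positions in [0, L); exactly
    round(2N*f) of them carry the mutator allele every generation.
    """
    rng = np.random.default_rng(seed)
    two_n = 2 * N
    k = int(round(two_n * f))
    if not 0 < k < two_n:
        raise ValueError("f must leave both carriers and non-carriers")
    pop: list[np.ndarray] = [np.empty(0) for _ in range(two_n)]
    # children 0..k-1 are carriers by construction each generation
    carrier = np.zeros(two_n, dtype=bool)
    carrier[:k] = True
    rate_car = mu * L * phi
    rate_wt = mu * L * (1.0 + (phi - 1.0) * f)

    for _ in range(g):
        carr_idx = np.flatnonzero(carrier)
        wt_idx = np.flatnonzero(~carrier)
        new_pop: list[np.ndarray] = []
        n_breaks = rng.poisson(rho * L, size=two_n)
        n_muts = rng.poisson(
            np.where(np.arange(two_n) < k, rate_car, rate_wt)
        )
        for i in range(two_n):
            pool = carr_idx if i < k else wt_idx
            lp = int(pool[rng.integers(pool.size)])
            partner = int(rng.integers(two_n))
            breaks = np.sort(rng.uniform(0.0, L, size=n_breaks[i]))
            child = _recombine(pop[lp], pop[partner], locus, breaks)
            if n_muts[i]:
                child = np.sort(
                    np.concatenate([child, rng.uniform(0.0, L, size=n_muts[i])])
                )
            new_pop.append(child)
        pop = new_pop
    return pop, carrier


def forward_carrier_excess(
    N: int,
    L: float,
    locus: float,
    mu: float,
    rho: float,
    phi: float,
    f: float,
    g: int,
    window: float,
    seed: int,
) -> float:
    """Mean derived-allele count within ``locus +- window`` among carriers
    minus the same mean among non-carriers, for one replicate."""
    pop, carrier = forward_population(N, L, locus, mu, rho, phi, f, g, seed)
    lo, hi = locus - window, locus + window
    counts = np.array(
        [np.count_nonzero((h >= lo) & (h < hi)) for h in pop], dtype=float
    )
    return float(counts[carrier].mean() - counts[~carrier].mean())
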