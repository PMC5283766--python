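"""Closed-form expectations for germline mutator-allele signatures.

A mutator allele multiplies the germline mutation rate of its carriers by a
factor ``phi``. While it segregates, the chromosomal segment linked to it
accumulates derived alleles faster than the population background, leaving a
haplotype signature that survives even after the allele is lost. This module
collects the closed-form quantities describing that signature:

* the per-site excess of derived alleles on carrier haplotypes, ``g*mu*(phi-1)``;
* the expected length of the segment around the focal locus that has escaped
  recombination since the allele arose, ``2/(g*rho)``;
* the expected number of excess mutations on that segment, ``2*mu*(phi-1)/rho``
  (independent of the allele's age);
* the selection coefficient acting against a mutator through the extra
  deleterious load it creates, ``s = -2*s_d*(phi-1)*U``;
* deterministic single-locus allele-frequency dynamics and the expected time
  to extinction of a weakly deleterious allele (diffusion quadrature, with a
  discrete Wright-Fisher simulator as an independent stochastic counterpart).

Rates are per base pair per generation; population size ``N`` counts diploids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .errors import InvalidParameterError, NoLossError

__all__ = [
    "MutatorModel",
    "DeleteriousLoad",
    "extra_mutations_per_site",
    "mean_segment_length",
    "extra_mutations_in_mean_segment",
    "mutator_selection_coefficient",
    "expected_background_derived",
    "deterministic_trajectory",
    "wf_extinction_time",
    "diffusion_extinction_time",
    "expected_carrier_excess",
]


@dataclass(frozen=True)
class MutatorModel:
    """Parameters of one mutator-allele scenario.

    Attributes
    ----------
    mu : float
        Wild-type mutation rate per bp per generation.
    rho : float
        Recombination rate per bp per generation.
    phi : float
        Mutation-rate multiplier in carriers (>= 1; 1 is neutral).
    g : int
        Generations since the mutator allele arose.
    s : float
        Selection coefficient of the homozygous mutator (<= 0 if deleterious).
    h : float
        Dominance coefficient; heterozygote fitness is ``1 + h*s``.
    p0 : float
        Allele frequency at origin, in (0, 1).
    N : int
        Diploid effective population size.
    """

    mu: float = 1.2e-8
    rho: float = 1.26e-8
    phi: float = 5.0
    g: int = 20_000
    s: float = -0.0002
    h: float = 0.5
    p0: float = 0.2
    N: int = 10_000

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise InvalidParameterError("mu must be > 0")
        if self.rho <= 0:
            raise InvalidParameterError("rho must be > 0")
        if self.phi < 1:
            raise InvalidParameterError("phi must be >= 1")
        if self.g < 0:
            raise InvalidParameterError("g must be >= 0")
        if not 0 < self.p0 < 1:
            raise InvalidParameterError("p0 must lie in (0, 1)")
        if self.N < 2:
            raise InvalidParameterError("N must be >= 2")
        if not 0 <= self.h <= 1:
            raise InvalidParameterError("h must lie in [0, 1]")


@dataclass(frozen=True)
class DeleteriousLoad:
    """Genome-wide deleterious-mutation parameters behind selection against a
    mutator.

    ``s_d`` is the mean heterozygous selective disadvantage of a single
    deleterious mutation (magnitude), ``U`` the genomic deleterious mutation
    rate per generation, and ``delta_U`` the increase in ``U`` the mutator
    causes. ``heterozygosity`` is per-bp pairwise diversity.
    """

    s_d: float
    U: float
    phi: float = 1.0
    heterozygosity: float = 0.001
    delta_U: float = field(init=False)

    def __post_init__(self) -> None:
        if self.s_d < 0 or self.U < 0:
            raise InvalidParameterError("s_d and U must be >= 0")
        if self.phi < 1:
            raise InvalidParameterError("phi must be >= 1")
        if not 0 < self.heterozygosity < 0.01:
            raise InvalidParameterError("heterozygosity must lie in (0, 0.01)")
        object.__setattr__(self, "delta_U", (self.phi - 1.0) * self.U)


def extra_mutations_per_site(g: float, mu: float, phi: float) -> float:
    """Expected excess of derived alleles per site on a carrier haplotype,
    ``g * mu * (phi - 1)``."""
    if g < 0:
        raise InvalidParameterError("g must be >= 0")
    if mu <= 0:
        raise InvalidParameterError("mu must be > 0")
    if phi < 1:
        raise InvalidParameterError("phi must be >= 1")
    return g * mu * (phi - 1.0)


def mean_segment_length(g: float, rho: float) -> float:
    """Expected length (bp) of the segment around the focal locus unbroken by
    recombination for ``g`` generations: ``2 / (g * rho)``."""
    if g <= 0:
        raise InvalidParameterError("g must be > 0")
    if rho <= 0:
        raise InvalidParameterError("rho must be > 0")
    return 2.0 / (g * rho)


def extra_mutations_in_mean_segment(mu: float, phi: float, rho: float) -> float:
    """Expected excess mutation count on a segment of mean unrecombined
    length, ``2 * mu * (phi - 1) / rho``; independent of the allele's age."""
    if mu <= 0 or rho <= 0:
        raise InvalidParameterError("mu and rho must be > 0")
    if phi < 1:
        raise InvalidParameterError("phi must be >= 1")
    return 2.0 * mu * (phi - 1.0) / rho


def mutator_selection_coefficient(
    s_d: float, U: float, phi: float, h_mut: float | None = None
) -> float:
    """Heterozygous selective disadvantage of a mutator allele.

    The base form assumes the constituent deleterious mutations are
    codominant: ``s = -2 * s_d * (phi - 1) * U``. When ``h_mut`` (the
    dominance coefficient of the constituent mutations) is supplied, the
    coefficient is scaled by ``h_mut / 0.5`` so that ``h_mut = 0.5`` recovers
    the codominant base form.
    """
    if s_d < 0 or U < 0:
        raise InvalidParameterError("s_d and U must be >= 0")
    if phi < 1:
        raise InvalidParameterError("phi must be >= 1")
    base = -2.0 * s_d * (phi - 1.0) * U
    if h_mut is None:
        return base
    if not 0 <= h_mut <= 1:
        raise InvalidParameterError("h_mut must lie in [0, 1]")
    return base * (h_mut / 0.5)


def expected_background_derived(heterozygosity: float, length: float) -> float:
    """Expected derived-allele count on a background (non-carrier) haplotype
    over ``length`` bp: ``heterozygosity * length``."""
    if heterozygosity < 0 or length < 0:
        raise InvalidParameterError("inputs must be >= 0")
    return heterozygosity * length


def deterministic_trajectory(
    p0: float, s: float, h: float, T: int
) -> np.ndarray:
    """Deterministic allele-frequency trajectory over ``T`` generations.

    Genotype fitnesses are ``1+s`` (mutator homozygote), ``1+h*s``
    (heterozygote) and ``1`` (wild type); the update is the standard
    single-locus recursion ``p' = p (p w_AA + q w_Aa) / wbar``.

    Returns an array of length ``T + 1`` with ``f[0] = p0``.
    """
    if not 0 < p0 < 1:
        raise InvalidParameterError("p0 must lie in (0, 1)")
    if T < 0:
        raise InvalidParameterError("T must be >= 0")
    w_aa = 1.0 + s
    w_het = 1.0 + h * s
    f = np.empty(T + 1)
    f[0] = p0
    p = p0
    for t in range(T):
        q = 1.0 - p
        wbar = p * p * w_aa + 2.0 * p * q * w_het + q * q
        p = p * (p * w_aa + q * w_het) / wbar
        f[t + 1] = p
    return f


def _wf_step(rng: np.random.Generator, p: np.ndarray, s: float, h: float, N: int) -> np.ndarray:
    """One Wright-Fisher generation: deterministic selection followed by
    binomial sampling of 2N allele copies."""
    q = 1.0 - p
    w_aa = 1.0 + s
    w_het = 1.0 + h * s
    wbar = p * p * w_aa + 2.0 * p * q * w_het + q * q
    p_sel = p * (p * w_aa + q * w_het) / wbar
    return rng.binomial(2 * N, p_sel) / (2.0 * N)


def wf_extinction_time(
    N: int,
    p0: float,
    s: float,
    h: float = 0.5,
    reps: int = 500,
    seed: int = 0,
    max_generations: int | None = None,
):
    """Simulated mean time to loss of an allele under discrete Wright-Fisher
    reproduction.

    Selection acts deterministically on the expected frequency each
    generation, then 2N allele copies are drawn binomially. Replicates that
    fix (expected to be rare for a deleterious allele) are excluded from the
    mean and reported separately.

    Returns
    -------
    dict with keys ``mean`` (mean generations to loss among lost replicates),
    ``se`` (Monte-Carlo standard error of that mean), ``n_lost``, ``n_fixed``,
    ``times`` (loss times), and the unconditional absorption-time summary
    ``mean_absorption`` / ``se_absorption`` over all replicates (loss or
    fixation), the quantity the diffusion quadrature predicts by default.
    """
    if reps < 1:
        raise InvalidParameterError("reps must be >= 1")
    if N < 2:
        raise InvalidParameterError("N must be >= 2")
    if p0 == 0:
        zeros = np.zeros(reps)
        return {"mean": 0.0, "se": 0.0, "n_lost": reps, "n_fixed": 0,
                "times": zeros, "mean_absorption": 0.0, "se_absorption": 0.0}
    if max_generations is None:
        max_generations = 400 * N
    rng = np.random.default_rng(seed)
    p = np.full(reps, float(p0))
    active = np.ones(reps, dtype=bool)
    absorb_time = np.full(reps, -1.0)
    fixed = np.zeros(reps, dtype=bool)
    t = 0
    while active.any() and t < max_generations:
        t += 1
        idx = np.flatnonzero(active)
        x = _wf_step(rng, p[idx], s, h, N)
        p[idx] = x
        lost = idx[x == 0.0]
        fix = idx[x == 1.0]
        absorb_time[lost] = t
        absorb_time[fix] = t
        fixed[fix] = True
        active[lost] = False
        active[fix] = False
    done = absorb_time >= 0
    times = absorb_time[done & ~fixed]
    if times.size == 0:
        raise NoLossError("no replicate ended in allele loss")
    all_times = absorb_time[done]
    mean = float(times.mean())
    se = float(times.std(ddof=1) / math.sqrt(times.size)) if times.size > 1 else float("inf")
    se_abs = (
        float(all_times.std(ddof=1) / math.sqrt(all_times.size))
        if all_times.size > 1
        else float("inf")
    )
    return {"mean": mean, "se": se, "n_lost": int(times.size),
            "n_fixed": int(fixed.sum()), "times": times,
            "mean_absorption": float(all_times.mean()),
            "se_absorption": se_abs}


def diffusion_extinction_time(
    N: int, p0: float, s: float, h: float = 0.5, conditional_on_loss: bool = False
) -> float:
    """Expected generations to absorption under the diffusion approximation
    with additive (codominant) selection.

    Uses the standard mean-absorption-time Green's function with scale
    density ``exp(-2*N*s*x)`` (codominant selection: per-copy advantage
    ``s/2``, drift ``(s/2) x (1-x)``, variance ``x(1-x)/(2N)``). The neutral
    limit reduces to ``-4N (p ln p + q ln q)``.

    With ``conditional_on_loss=True``, the sojourn density is reweighted by
    the probability of eventual loss, giving the mean absorption time among
    paths that end in loss.
    """
    if N < 2:
        raise InvalidParameterError("N must be >= 2")
    if not 0 < p0 < 1:
        raise InvalidParameterError("p0 must lie in (0, 1)")
    if h != 0.5:
        # The closed diffusion form used here assumes genic (additive)
        # selection; the heterozygote effect h*s with h=0.5 maps onto it.
        raise InvalidParameterError(
            "diffusion_extinction_time supports codominant selection (h=0.5) only"
        )
    alpha = 2.0 * N * s
    if abs(alpha) < 1e-10:
        S = lambda x: x  # noqa: E731
        psi = lambda x: 1.0  # noqa: E731
    else:
        S = lambda x: -math.expm1(-alpha * x) / alpha  # noqa: E731
        psi = lambda x: math.exp(-alpha * x)  # noqa: E731
    S1 = S(1.0)
    u_fix = S(p0) / S1

    def V(x: float) -> float:
        return x * (1.0 - x) / (2.0 * N)

    def green(x: float) -> float:
        if x >= p0:
            return 2.0 * u_fix * (S1 - S(x)) / (V(x) * psi(x))
        return 2.0 * (1.0 - u_fix) * S(x) / (V(x) * psi(x))

    if conditional_on_loss:
        u_loss_p = 1.0 - u_fix

        def integrand(x: float) -> float:
            return green(x) * (1.0 - S(x) / S1) / u_loss_p
    else:
        integrand = green

    val, err = quad(integrand, 0.0, 1.0, points=[p0], limit=400, epsrel=1e-8)
    if not math.isfinite(val):
        from .errors import NumericalFailureError

        raise NumericalFailureError("absorption-time quadrature did not converge")
    return float(val)


def expected_carrier_excess(
    model: MutatorModel, max_distance: float, n_points: int = 400
) -> float:
    """Expected excess of derived alleles on a present-day carrier haplotype
    within ``max_distance`` bp on either side of the focal locus.

    A site at distance ``x`` stays attached to the lineage that carries the
    focal locus back to time ``t`` with probability ``exp(-rho*x*t)``. While
    attached, a carrier lineage mutates at ``phi*mu`` versus the non-carrier
    expectation ``mu*(1 + f(t)(phi-1))``, a differential of
    ``mu*(phi-1)*(1-f(t))`` per generation; once detached, material from
    carrier- and non-carrier-conditioned haplotypes enters the same
    background-resampling process, so its expected contribution cancels from
    the carrier/non-carrier difference. Integrating the attached-phase
    differential over time and distance (both flanks) gives the expected
    excess; as ``max_distance -> inf`` and ``f -> 0`` this approaches
    ``2*mu*(phi-1)/rho``.
    """
    if max_distance <= 0:
        raise InvalidParameterError("max_distance must be > 0")
    f_fwd = deterministic_trajectory(model.p0, model.s, model.h, model.g)
    # Backward time tau: frequency g - tau generations after origin.
    f_back = f_fwd[::-1]
    one_minus_f = 1.0 - f_back
    taus = np.arange(model.g + 1, dtype=float)
    xs = np.linspace(0.0, max_distance, n_points)
    # For each distance, integrate the differential rate over backward time.
    vals = np.empty_like(xs)
    for i, x in enumerate(xs):
        surv = np.exp(-model.rho * x * taus)
        vals[i] = model.mu * (model.phi - 1.0) * np.sum(one_minus_f * surv)
    return float(2.0 * np.trapezoid(vals, xs))
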