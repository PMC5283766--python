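"""Coalescent simulation of a genomic region containing a mutator locus.

The central object is a two-background structured coalescent with
recombination, run backward in time conditional on the deterministic
frequency trajectory of the mutator allele:

* sampled haplotypes are assigned carrier status Bernoulli(f_now);
* lineages coalesce only within their allelic background (carrier or
  wild type), at a rate inversely proportional to that background's
  population frequency;
* recombination occurs at rate ``rho`` per bp along the interval spanned by
  a lineage's ancestral material and the focal locus; the material on the
  far side of the breakpoint from the locus moves to a chromosome drawn at
  random from the population, i.e. to the carrier background with
  probability equal to the current allele frequency;
* at the allele's origin all carrier lineages merge into the wild-type
  background and the process continues as a neutral coalescent with
  recombination until every interval of the region has reached its MRCA;
* mutations fall on branches as a Poisson process at ``phi*mu`` per bp per
  generation while a lineage is in the carrier background and at the
  expectation ``mu*(1 + f(t)*(phi-1))`` otherwise (a non-carrier chromosome
  is paired with a carrier, and thereby mutates at the elevated rate, with
  probability equal to the allele frequency).

Neutral demographic null simulations (single panmictic population, and five
populations splitting 100 kyr ago) are delegated to msprime, and a simple
multinucleotide-mutation clustering step can be layered on any simulated
sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import msprime
import numpy as np

from .errors import (
    AlleleLostError,
    InvalidParameterError,
    PairingError,
)
from .theory import MutatorModel, deterministic_trajectory

__all__ = [
    "RegionSpec",
    "HaplotypeSample",
    "NullDemography",
    "MnmConfig",
    "simulate_mutator_region",
    "simulate_null",
    "add_multinucleotide_mutations",
    "write_vcf",
    "write_panel",
    "read_hapmap_genetic_map",
]


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class RegionSpec:
    """A simulated genomic region.

    ``recomb_map`` is either ``None`` (uniform rate taken from the model's
    ``rho``), a float (uniform per-bp per-generation rate), or a sequence of
    ``(start, end, rate)`` pieces covering [0, length).
    """

    length: int = 100_000
    locus_position: int = 50_000
    recomb_map: float | Sequence[tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.locus_position <= self.length:
            raise InvalidParameterError("locus_position must lie within [0, length]")
        if isinstance(self.recomb_map, (int, float)) and self.recomb_map < 0:
            raise InvalidParameterError("recombination rate must be >= 0")

    def rate_pieces(self, default_rate: float) -> list[tuple[float, float, float]]:
        if self.recomb_map is None:
            return [(0.0, float(self.length), default_rate)]
        if isinstance(self.recomb_map, (int, float)):
            return [(0.0, float(self.length), float(self.recomb_map))]
        pieces = [(float(a), float(b), float(r)) for a, b, r in self.recomb_map]
        if any(r < 0 for _, _, r in pieces):
            raise InvalidParameterError("recombination rates must be >= 0")
        return pieces


@dataclass
class HaplotypeSample:
    """Phased haplotypes as a binary derived/ancestral matrix.

    ``calls`` has shape (n_haplotypes, n_sites); ``positions`` are strictly
    increasing bp coordinates within ``[0, length)`` (0-based). ``carrier``
    flags haplotypes carrying the mutator allele at present (None for null
    simulations); ``population`` labels each haplotype.
    """

    positions: np.ndarray
    calls: np.ndarray
    length: int
    carrier: np.ndarray | None = None
    population: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        self.calls = np.asarray(self.calls, dtype=np.uint8)
        if self.calls.ndim != 2 or self.calls.shape[1] != self.positions.size:
            raise InvalidParameterError("calls must be (n_haplotypes, n_sites)")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise InvalidParameterError("positions must be strictly increasing")
        if self.population is None:
            self.population = np.array(["pop0"] * self.calls.shape[0])
        else:
            self.population = np.asarray(self.population)

    @property
    def n_haplotypes(self) -> int:
        return self.calls.shape[0]

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    def derived_counts(self) -> np.ndarray:
        """Total derived-allele count per haplotype."""
        return self.calls.sum(axis=1)


@dataclass(frozen=True)
class NullDemography:
    """Neutral null scenario: a single panmictic population, or five
    populations splitting ``split_time`` years ago."""

    mode: str = "single"  # "single" | "split"
    n_pops: int = 1
    split_time: float = 100_000.0  # years
    generation_time: float = 25.0
    theta: float = 0.001  # 4*Ne*mu per bp
    sample_size: int = 100  # haplotypes

    def __post_init__(self) -> None:
        if self.mode not in ("single", "split"):
            raise InvalidParameterError("mode must be 'single' or 'split'")
        if self.theta <= 0:
            raise InvalidParameterError("theta must be > 0")
        if self.mode == "split" and self.n_pops < 2:
            raise InvalidParameterError("split mode requires n_pops >= 2")
        if self.mode == "single" and self.n_pops != 1:
            raise InvalidParameterError("single mode requires n_pops == 1")
        if self.sample_size < 2:
            raise InvalidParameterError("sample_size must be >= 2")


@dataclass(frozen=True)
class MnmConfig:
    """Multinucleotide-mutation clustering: each mutation event spawns an
    extra nearby mutation on the same branch with probability
    ``event_fraction``, within ``max_distance`` bp."""

    event_fraction: float = 0.02
    max_distance: int = 100

    def __post_init__(self) -> None:
        if not 0 <= self.event_fraction <= 1:
            raise InvalidParameterError("event_fraction must lie in [0, 1]")
        if self.max_distance < 1:
            raise InvalidParameterError("max_distance must be >= 1")


# ---------------------------------------------------------------------------
# Structured coalescent internals

_CARRIER, _WILD = 0, 1


class _RecombMap:
    """Cumulative recombination map over [0, length)."""

    def __init__(self, pieces: list[tuple[float, float, float]], length: float):
        pieces = sorted(pieces)
        self.starts = np.array([p[0] for p in pieces])
        self.ends = np.array([p[1] for p in pieces])
        self.rates = np.array([p[2] for p in pieces])
        if self.starts[0] > 0 or self.ends[-1] < length:
            raise InvalidParameterError("recombination map must cover the region")
        self.cum = np.concatenate(
            [[0.0], np.cumsum(self.rates * (self.ends - self.starts))]
        )

    def mass(self, a: float, b: float) -> float:
        """Integrated rate over [a, b]."""
        return self._cum_at(b) - self._cum_at(a)

    def _cum_at(self, x: float) -> float:
        i = int(np.searchsorted(self.ends, x, side="left"))
        i = min(i, len(self.rates) - 1)
        return float(self.cum[i] + self.rates[i] * max(0.0, x - self.starts[i]))

    def sample_breakpoint(self, a: float, b: float, u: float) -> float:
        """Position x in [a, b] with cumulative mass fraction u."""
        target = self._cum_at(a) + u * self.mass(a, b)
        i = int(np.searchsorted(self.cum, target, side="right")) - 1
        i = min(max(i, 0), len(self.rates) - 1)
        if self.rates[i] == 0:
            return self.ends[i]
        return float(self.starts[i] + (target - self.cum[i]) / self.rates[i])


class _Lineage:
    __slots__ = ("segments", "background", "last_update")

    def __init__(self, segments, background, tau):
        # segments: sorted disjoint list of (start, end, frozenset of samples)
        self.segments = segments
        self.background = background
        self.last_update = tau

    def hull(self):
        return self.segments[0][0], self.segments[-1][1]

    def material_length(self):
        return sum(e - s for s, e, _ in self.segments)


def _merge_segments(a, b):
    """Union of two ancestral-material structures, splitting at boundaries
    and unioning sample sets on overlaps."""
    bounds = sorted({x for s, e, _ in a + b for x in (s, e)})
    out = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        mid = 0.5 * (lo + hi)
        sets = [ss for s, e, ss in a if s <= mid < e]
        sets += [ss for s, e, ss in b if s <= mid < e]
        if not sets:
            continue
        merged = frozenset().union(*sets)
        if out and out[-1][1] == lo and out[-1][2] == merged:
            out[-1] = (out[-1][0], hi, merged)
        else:
            out.append((lo, hi, merged))
    return out


def _split_segments(segments, x):
    """Split material at breakpoint x into (left-of-x, right-of-x)."""
    left, right = [], []
    for s, e, ss in segments:
        if e <= x:
            left.append((s, e, ss))
        elif s >= x:
            right.append((s, e, ss))
        else:
            left.append((s, x, ss))
            right.append((x, e, ss))
    return left, right


def simulate_mutator_region(
    model: MutatorModel,
    region: RegionSpec | None = None,
    n: int = 100,
    seed: int = 0,
    block: float = 250.0,
) -> HaplotypeSample:
    """Simulate phased haplotypes for a region containing a mutator locus.

    Parameters
    ----------
    model : MutatorModel
        Mutation, recombination, selection and trajectory parameters.
    region : RegionSpec
        Region length, focal-locus position and recombination map.
    n : int
        Number of sampled haplotypes.
    seed : int
        Random seed; fixed seed gives bit-identical output.
    block : float
        Generation span over which time-varying rates are bounded for the
        thinning step of the event scheduler (numerical knob only).

    Returns
    -------
    HaplotypeSample with carrier flags.
    """
    if region is None:
        region = RegionSpec()
    if n < 2:
        raise InvalidParameterError("n must be >= 2")
    if n > 2 * model.N:
        raise InvalidParameterError("cannot sample more haplotypes than 2N")

    rng = np.random.default_rng(seed)
    L = float(region.length)
    locus = float(region.locus_position)
    rmap = _RecombMap(region.rate_pieces(model.rho), L)
    g = model.g

    # Forward trajectory, then backward view phi(tau) = f at tau generations
    # before the present; Phi is its running integral (trapezoid on the
    # per-generation grid).
    if g > 0:
        f_fwd = deterministic_trajectory(model.p0, model.s, model.h, g)
        f_back = f_fwd[::-1].copy()
        if f_back[0] < 1.0 / (2 * model.N):
            raise AlleleLostError(
                "deterministic trajectory reaches loss before the present"
            )
    else:
        f_back = np.array([model.p0])
    phi_cum = np.concatenate([[0.0], np.cumsum(0.5 * (f_back[1:] + f_back[:-1]))])

    def freq(tau: float) -> float:
        if g == 0 or tau >= g:
            return 0.0
        return float(np.interp(tau, np.arange(g + 1), f_back))

    def freq_integral(a: float, b: float) -> float:
        # integral of f over backward time [a, b]
        if g == 0:
            return 0.0
        grid = np.arange(g + 1)
        ca = np.interp(min(a, g), grid, phi_cum)
        cb = np.interp(min(b, g), grid, phi_cum)
        return float(cb - ca)

    f_now = f_back[0] if g > 0 else 0.0
    carrier = rng.random(n) < f_now if g > 0 else np.zeros(n, dtype=bool)

    lineages: list[_Lineage] = []
    for i in range(n):
        bg = _CARRIER if carrier[i] else _WILD
        lineages.append(_Lineage([(0.0, L, frozenset([i]))], bg, 0.0))

    full = frozenset(range(n))
    mutations: list[tuple[float, frozenset]] = []
    mu, phi_mult = model.mu, model.phi
    two_n_pop = 2.0 * model.N

    def flush(lin: _Lineage, tau: float) -> None:
        """Place mutations accumulated on this lineage since its last update."""
        a, b = lin.last_update, tau
        if b <= a or not lin.segments:
            lin.last_update = tau
            return
        if lin.background == _CARRIER:
            # carrier lineages exist only during [0, g]
            per_bp = mu * phi_mult * (b - a)
        else:
            per_bp = mu * ((b - a) + (phi_mult - 1.0) * freq_integral(a, b))
        lam = per_bp * lin.material_length()
        k = rng.poisson(lam) if lam > 0 else 0
        if k:
            lens = np.array([e - s for s, e, _ in lin.segments])
            probs = lens / lens.sum()
            seg_idx = rng.choice(len(lens), size=k, p=probs)
            for si in seg_idx:
                s, e, ss = lin.segments[si]
                mutations.append((float(rng.uniform(s, e)), ss))
        lin.last_update = tau

    def strip_mrca(lin: _Lineage) -> bool:
        """Remove intervals that reached the grand MRCA; True if material remains."""
        lin.segments = [seg for seg in lin.segments if seg[2] != full]
        return bool(lin.segments)

    tau = 0.0
    max_tau = g + 400.0 * model.N  # generous safety ceiling
    while lineages:
        if tau > max_tau:
            raise RuntimeError("coalescent failed to complete (safety ceiling hit)")
        k_c = sum(1 for l in lineages if l.background == _CARRIER)
        k_w = len(lineages) - k_c
        rec_rates = np.array(
            [
                rmap.mass(min(l.hull()[0], locus), max(l.hull()[1], locus))
                for l in lineages
            ]
        )
        rec_total = float(rec_rates.sum())

        in_phase1 = tau < g
        if in_phase1:
            block_end = min(g, (math.floor(tau / block) + 1) * block)
            f0, f1 = freq(tau), freq(block_end)
            fmin, fmax = min(f0, f1), max(f0, f1)
            coal_c_max = (
                k_c * (k_c - 1) / 2.0 / (two_n_pop * fmin) if k_c > 1 and fmin > 0 else 0.0
            )
            coal_w_max = (
                k_w * (k_w - 1) / 2.0 / (two_n_pop * (1.0 - fmax)) if k_w > 1 else 0.0
            )
        else:
            block_end = math.inf
            coal_c_max = 0.0  # no carrier background after the origin
            coal_w_max = k_w * (k_w - 1) / 2.0 / two_n_pop if k_w > 1 else 0.0

        r_bound = coal_c_max + coal_w_max + rec_total
        if r_bound <= 0:
            if math.isinf(block_end):
                break  # nothing can happen any more
            tau = block_end
        else:
            dt = rng.exponential(1.0 / r_bound)
            if tau + dt >= block_end:
                tau = block_end
            else:
                tau += dt
                f_tau = freq(tau)
                coal_c = (
                    k_c * (k_c - 1) / 2.0 / (two_n_pop * f_tau)
                    if k_c > 1 and f_tau > 0
                    else 0.0
                )
                one_minus = 1.0 - f_tau
                coal_w = (
                    k_w * (k_w - 1) / 2.0 / (two_n_pop * one_minus) if k_w > 1 else 0.0
                )
                u = rng.uniform(0.0, r_bound)
                if u < coal_c:
                    _coalesce(lineages, _CARRIER, tau, rng, flush, strip_mrca)
                elif u < coal_c + coal_w:
                    _coalesce(lineages, _WILD, tau, rng, flush, strip_mrca)
                elif u < coal_c + coal_w + rec_total:
                    _recombine(
                        lineages, rec_rates, tau, rng, flush, rmap, locus, f_tau
                    )
                # else: thinned -> no event

        if in_phase1 and tau >= g:
            # allele origin: carrier lineages join the wild-type background
            for lin in lineages:
                if lin.background == _CARRIER:
                    flush(lin, g)
                    lin.background = _WILD

    positions, calls = _build_matrix(mutations, n, L, rng)
    return HaplotypeSample(
        positions=positions,
        calls=calls,
        length=int(L),
        carrier=carrier,
        population=np.array(["pop0"] * n),
        meta={"seed": seed, "model": model, "region": region, "n": n},
    )


def _coalesce(lineages, background, tau, rng, flush, strip_mrca):
    idx = [i for i, l in enumerate(lineages) if l.background == background]
    i, j = rng.choice(len(idx), size=2, replace=False)
    a, b = lineages[idx[i]], lineages[idx[j]]
    flush(a, tau)
    flush(b, tau)
    merged = _merge_segments(a.segments, b.segments)
    child = _Lineage(merged, background, tau)
    for k in sorted((idx[i], idx[j]), reverse=True):
        del lineages[k]
    if strip_mrca(child):
        lineages.append(child)


def _recombine(lineages, rec_rates, tau, rng, flush, rmap, locus, f_tau):
    cum = np.cumsum(rec_rates)
    pick = int(np.searchsorted(cum, rng.uniform(0.0, cum[-1]), side="right"))
    pick = min(pick, len(lineages) - 1)
    lin = lineages[pick]
    lo, hi = lin.hull()
    a, b = min(lo, locus), max(hi, locus)
    x = rmap.sample_breakpoint(a, b, rng.random())
    flush(lin, tau)
    left, right = _split_segments(lin.segments, x)
    near, far = (left, right) if locus <= x else (right, left)
    new_bg = _CARRIER if rng.random() < f_tau else _WILD
    if not near:
        # the entire material detaches onto a random chromosome
        lin.background = new_bg
        return
    if not far:
        return  # breakpoint outside the material on the locus side: no-op
    lin.segments = near
    lineages.append(_Lineage(far, new_bg, tau))


def _build_matrix(mutations, n, length, rng):
    """Sorted integer positions + binary calls matrix from mutation records.

    Infinite-sites positions are continuous; they are rounded to integer bp
    and collisions resolved by moving to the nearest free coordinate.
    """
    taken: set[int] = set()
    placed = []
    for pos, ss in sorted(mutations):
        p = int(round(pos))
        step = 0
        while True:
            for cand in (p - step, p + step) if step else (p,):
                if 0 <= cand < length and cand not in taken:
                    p = cand
                    break
            else:
                step += 1
                continue
            break
        taken.add(p)
        placed.append((p, ss))
    placed.sort(key=lambda t: t[0])
    positions = np.array([p for p, _ in placed], dtype=np.int64)
    calls = np.zeros((n, len(placed)), dtype=np.uint8)
    for j, (_, ss) in enumerate(placed):
        calls[list(ss), j] = 1
    return positions, calls


# ---------------------------------------------------------------------------
# Neutral null simulations (msprime)


def simulate_null(
    demog: NullDemography,
    region: RegionSpec | None = None,
    seed: int = 0,
    Ne: float = 10_000.0,
    default_rho: float = 1.26e-8,
) -> HaplotypeSample:
    """Neutral coalescent simulation under a single-population or
    five-population-split demography, scaled so per-bp diversity is
    ``theta``."""
    if region is None:
        region = RegionSpec(length=1_000_000, locus_position=500_000)
    mu = demog.theta / (4.0 * Ne)
    # Samples are haploid lineages (ploidy=1); msprime's coalescent timescale
    # is then the haploid population size, so a diploid effective size Ne
    # corresponds to 2*Ne haploid lineages (pairwise diversity 4*Ne*mu).
    hap_size = 2.0 * Ne
    pieces = region.rate_pieces(default_rho)
    if len(pieces) == 1:
        rate_map = pieces[0][2]
    else:
        pos = [p[0] for p in pieces] + [pieces[-1][1]]
        rate_map = msprime.RateMap(position=pos, rate=[p[2] for p in pieces])

    if demog.mode == "single":
        ts = msprime.sim_ancestry(
            samples=demog.sample_size,
            ploidy=1,
            population_size=hap_size,
            sequence_length=region.length,
            recombination_rate=rate_map,
            random_seed=seed + 1,
        )
        pops = np.array(["pop0"] * demog.sample_size)
    else:
        split_gen = demog.split_time / demog.generation_time
        d = msprime.Demography()
        for i in range(demog.n_pops):
            d.add_population(name=f"pop{i}", initial_size=hap_size)
        d.add_population(name="anc", initial_size=hap_size)
        d.add_population_split(
            time=split_gen,
            derived=[f"pop{i}" for i in range(demog.n_pops)],
            ancestral="anc",
        )
        per_pop = demog.sample_size // demog.n_pops
        if per_pop < 1:
            raise InvalidParameterError("sample_size too small for n_pops")
        ts = msprime.sim_ancestry(
            samples={f"pop{i}": per_pop for i in range(demog.n_pops)},
            ploidy=1,
            demography=d,
            sequence_length=region.length,
            recombination_rate=rate_map,
            random_seed=seed + 1,
        )
        pops = np.array(
            [f"pop{i}" for i in range(demog.n_pops) for _ in range(per_pop)]
        )

    ts = msprime.sim_mutations(
        ts,
        rate=mu,
        model=msprime.BinaryMutationModel(),
        random_seed=seed + 2,
        discrete_genome=True,
    )
    gm = ts.genotype_matrix()  # sites x samples; 0 = ancestral
    derived = (gm > 0).astype(np.uint8).T
    positions = np.array([s.position for s in ts.sites()], dtype=np.int64)
    seg = (derived.sum(axis=0) > 0) & (derived.sum(axis=0) < derived.shape[0])
    return HaplotypeSample(
        positions=positions[seg],
        calls=derived[:, seg],
        length=region.length,
        carrier=None,
        population=pops,
        meta={"seed": seed, "demography": demog, "region": region},
    )


# ---------------------------------------------------------------------------
# Multinucleotide mutation clustering


def add_multinucleotide_mutations(
    sample: HaplotypeSample, cfg: MnmConfig, seed: int = 0
) -> HaplotypeSample:
    """Add clustered mutations: each site, with probability
    ``cfg.event_fraction``, spawns one extra site within ``cfg.max_distance``
    bp carried by exactly the same haplotypes (same branch)."""
    rng = np.random.default_rng(seed)
    spawn = rng.random(sample.n_sites) < cfg.event_fraction
    taken = set(int(p) for p in sample.positions)
    new_positions = []
    new_cols = []
    for j in np.flatnonzero(spawn):
        base = int(sample.positions[j])
        offset = 0
        while offset == 0:
            offset = int(rng.integers(-cfg.max_distance, cfg.max_distance + 1))
        p = min(max(base + offset, 0), sample.length - 1)
        step = 0
        while p in taken:
            step += 1
            for cand in (p - step, p + step):
                if 0 <= cand < sample.length and cand not in taken:
                    p = cand
                    break
            else:
                continue
        taken.add(p)
        new_positions.append(p)
        new_cols.append(sample.calls[:, j])
    if not new_positions:
        return HaplotypeSample(
            positions=sample.positions.copy(),
            calls=sample.calls.copy(),
            length=sample.length,
            carrier=None if sample.carrier is None else sample.carrier.copy(),
            population=sample.population.copy(),
            meta=dict(sample.meta, mnm=cfg),
        )
    all_pos = np.concatenate([sample.positions, np.array(new_positions)])
    all_calls = np.concatenate([sample.calls, np.stack(new_cols, axis=1)], axis=1)
    order = np.argsort(all_pos, kind="stable")
    return HaplotypeSample(
        positions=all_pos[order],
        calls=all_calls[:, order],
        length=sample.length,
        carrier=None if sample.carrier is None else sample.carrier.copy(),
        population=sample.population.copy(),
        meta=dict(sample.meta, mnm=cfg),
    )


# ---------------------------------------------------------------------------
# VCF / panel output


def write_vcf(
    sample: HaplotypeSample, path, chrom: str = "1", sample_prefix: str = "S"
) -> None:
    """Write the sample as a phased VCF 4.2 with INFO/AA ancestral-allele
    annotation, pairing haplotypes (2i, 2i+1) into diploid sample i.

    The ancestral base is written as uppercase REF ('A'), the derived allele
    as ALT ('G'); derived calls become ALT alleles in phased GT fields.
    """
    if sample.n_haplotypes % 2 != 0:
        raise PairingError("need an even number of haplotypes to form diploids")
    n_dip = sample.n_haplotypes // 2
    names = [f"{sample_prefix}{i}" for i in range(n_dip)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={sample.length}>\n")
        fh.write(
            '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral Allele">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(names)
            + "\n"
        )
        for j in range(sample.n_sites):
            pos1 = int(sample.positions[j]) + 1  # VCF is 1-based
            col = sample.calls[:, j]
            gts = "\t".join(
                f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(n_dip)
            )
            fh.write(f"{chrom}\t{pos1}\t.\tA\tG\t.\tPASS\tAA=A\tGT\t{gts}\n")


def write_panel(sample: HaplotypeSample, path, sample_prefix: str = "S") -> None:
    """Sidecar sample panel TSV (sample, pop, super_pop), one row per diploid."""
    if sample.n_haplotypes % 2 != 0:
        raise PairingError("need an even number of haplotypes to form diploids")
    with open(path, "w") as fh:
        fh.write("sample\tpop\tsuper_pop\n")
        for i in range(sample.n_haplotypes // 2):
            pop = str(sample.population[2 * i])
            fh.write(f"{sample_prefix}{i}\t{pop}\t{pop}\n")


def read_hapmap_genetic_map(path) -> list[tuple[float, float, float]]:
    """Read a 2-column genetic map TSV (position bp, rate cM/Mb; HapMap
    dialect, optional header) into (start, end, per-bp per-generation rate)
    pieces. 1 cM/Mb is converted as 1e-8 per bp per generation."""
    starts, rates = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            try:
                pos = float(parts[0])
            except ValueError:
                continue  # header
            starts.append(pos)
            rates.append(float(parts[1]) * 1e-8)
    pieces = []
    for i in range(len(starts) - 1):
        pieces.append((starts[i], starts[i + 1], rates[i]))
    return pieces
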