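"""Synthetic inputs for every pipeline stage.

These generators produce, without any external download, the data shapes
the analysis consumes: trio cohorts with a controllable carrier effect on
the de novo mutation count, spiked haplotype samples carrying a
mutator-like excess on a few haplotypes, and gene annotations with or
without repair genes clustered near chosen loci. Everything is a pure
function of its spec plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .simulate import HaplotypeSample
from .trios import TrioRecord

__all__ = [
    "TrioCohortSpec",
    "AnnotationSpec",
    "generate_trio_cohort",
    "spike_scan_fixture",
    "generate_annotation",
]


@dataclass(frozen=True)
class TrioCohortSpec:
    """Synthetic trio cohort.

    ``carrier_freq`` is the probability a parent carries at least one highly
    derived haplotype; under Hardy-Weinberg this implies an allele frequency
    ``1 - sqrt(1 - carrier_freq)`` from which 0/1/2 copies are drawn.
    De novo counts are Poisson with mean
    ``lambda0 + delta * hd_copies + age_slope * (age - mean age)``; ages are
    uniform on [20, 45] years.
    """

    n_trios: int = 100
    carrier_freq: float = 0.2
    lambda0: float = 45.0
    delta: float = 0.0
    age_slope: float | None = None
    parent_sex: str = "paternal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda0 <= 0:
            raise InvalidParameterError("lambda0 must be > 0")
        if not 0 <= self.carrier_freq <= 1:
            raise InvalidParameterError("carrier_freq must lie in [0, 1]")
        if self.n_trios < 1:
            raise InvalidParameterError("n_trios must be >= 1")


def generate_trio_cohort(spec: TrioCohortSpec) -> list[TrioRecord]:
    """Draw a trio cohort; hd_copies ~ Binomial(2, allele freq), dnm_count ~
    Poisson(lambda0 + delta*copies [+ age term]). Seeded and reproducible."""
    rng = np.random.default_rng(spec.seed)
    allele_freq = 1.0 - np.sqrt(1.0 - spec.carrier_freq)
    copies = rng.binomial(2, allele_freq, size=spec.n_trios)
    ages = rng.uniform(20.0, 45.0, size=spec.n_trios)
    mean_age = 32.5
    lam = spec.lambda0 + spec.delta * copies
    if spec.age_slope is not None:
        lam = lam + spec.age_slope * (ages - mean_age)
    if np.any(lam <= 0):
        raise InvalidParameterError("Poisson means must stay positive")
    counts = rng.poisson(lam)
    return [
        TrioRecord(
            family_id=f"fam{i}",
            parent_sex=spec.parent_sex,
            hd_copies=int(copies[i]),
            dnm_count=int(counts[i]),
            parent_age=float(ages[i]) if spec.age_slope is not None else None,
        )
        for i in range(spec.n_trios)
    ]


def spike_scan_fixture(
    base: HaplotypeSample,
    k: int,
    extra: int,
    window: tuple[int, int],
    seed: int = 0,
    jitter_fraction: float = 0.1,
) -> HaplotypeSample:
    """Spike a mutator-like signature into a neutral sample.

    ``extra`` new derived sites are placed at uniform positions within
    ``window``, each carried by the same ``k`` randomly chosen haplotypes
    (shared sites raise the window maximum while the trimmed mean stays
    stable for k <= n/4). Spiked haplotypes are drawn from distinct diploids
    whenever possible — carriers model unrelated individuals each bearing
    one highly derived haplotype, so the spike must not create spurious
    homozygotes that reject Hardy-Weinberg equilibrium. Each spiked
    haplotype additionally receives a small private jitter of about
    ``jitter_fraction * extra`` sites.
    """
    lo, hi = window
    if not 0 <= lo < hi <= base.length:
        raise InvalidParameterError("window must be a non-empty interval in the region")
    if k >= base.n_haplotypes:
        raise InvalidParameterError("k must be smaller than the number of haplotypes")
    rng = np.random.default_rng(seed)
    if extra == 0:
        return HaplotypeSample(
            positions=base.positions.copy(),
            calls=base.calls.copy(),
            length=base.length,
            carrier=None if base.carrier is None else base.carrier.copy(),
            population=base.population.copy(),
            meta=dict(base.meta, spiked=False),
        )
    n_dip = base.n_haplotypes // 2
    if base.n_haplotypes % 2 == 0 and k <= n_dip:
        diploids = rng.choice(n_dip, size=k, replace=False)
        chosen = 2 * diploids + rng.integers(0, 2, size=k)
    else:
        chosen = rng.choice(base.n_haplotypes, size=k, replace=False)
    taken = set(int(p) for p in base.positions)
    new_pos, new_cols = [], []

    def free_position() -> int:
        while True:
            p = int(rng.integers(lo, hi))
            if p not in taken:
                taken.add(p)
                return p

    for _ in range(extra):
        col = np.zeros(base.n_haplotypes, dtype=np.uint8)
        col[chosen] = 1
        new_pos.append(free_position())
        new_cols.append(col)
    n_jitter = rng.poisson(jitter_fraction * extra, size=k)
    for h, nj in zip(chosen, n_jitter):
        for _ in range(int(nj)):
            col = np.zeros(base.n_haplotypes, dtype=np.uint8)
            col[h] = 1
            new_pos.append(free_position())
            new_cols.append(col)

    all_pos = np.concatenate([base.positions, np.array(new_pos, dtype=np.int64)])
    all_calls = np.concatenate(
        [base.calls, np.stack(new_cols, axis=1)], axis=1
    )
    order = np.argsort(all_pos, kind="stable")
    carrier = np.zeros(base.n_haplotypes, dtype=bool)
    carrier[chosen] = True
    return HaplotypeSample(
        positions=all_pos[order],
        calls=all_calls[:, order],
        length=base.length,
        carrier=carrier,
        population=base.population.copy(),
        meta=dict(base.meta, spiked=True, spike_window=window, spike_k=k),
    )


@dataclass(frozen=True)
class AnnotationSpec:
    """Synthetic gene annotation over a single linear genome.

    ``clustering='near-loci'`` places every repair gene within
    ``cluster_radius`` of one of ``loci``; 'none' scatters genes uniformly.
    Gene lengths are uniform on [min_gene_length, max_gene_length].
    """

    genome_length: int = 10_000_000
    n_genes: int = 200
    n_repair: int = 20
    clustering: str = "none"  # "none" | "near-loci"
    loci: Sequence[int] = ()
    cluster_radius: int = 100_000
    min_gene_length: int = 5_000
    max_gene_length: int = 20_000
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repair > self.n_genes:
            raise InvalidParameterError("n_repair must be <= n_genes")
        if self.clustering not in ("none", "near-loci"):
            raise InvalidParameterError("clustering must be 'none' or 'near-loci'")
        if self.clustering == "near-loci" and not list(self.loci):
            raise InvalidParameterError("near-loci clustering requires loci")


def generate_annotation(spec: AnnotationSpec) -> pd.DataFrame:
    """Non-overlapping gene intervals with repair flags, as a BED-like frame
    (chrom, start, end, gene_id, repair; 0-based half-open)."""
    rng = np.random.default_rng(spec.seed)
    lengths = rng.integers(
        spec.min_gene_length, spec.max_gene_length + 1, size=spec.n_genes
    )
    if lengths.sum() > 0.5 * spec.genome_length:
        raise InvalidParameterError("genome too small to place genes sparsely")
    if spec.clustering == "near-loci":
        cluster_space = 2 * spec.cluster_radius * len(set(spec.loci))
        if lengths[: spec.n_repair].sum() > 0.8 * cluster_space:
            raise InvalidParameterError(
                "cluster regions too small for the repair genes; increase "
                "cluster_radius, add loci, or reduce n_repair/gene lengths"
            )
    starts = np.empty(spec.n_genes, dtype=np.int64)
    occupied: list[tuple[int, int]] = []

    def overlaps(s: int, e: int) -> bool:
        return any(s < oe and os_ < e for os_, oe in occupied)

    # repair genes first so clustering constraints always have room
    order = list(range(spec.n_genes))
    for gi in order:
        ln = int(lengths[gi])
        is_repair = gi < spec.n_repair
        for _attempt in range(10_000):
            if is_repair and spec.clustering == "near-loci":
                locus = int(rng.choice(np.asarray(list(spec.loci))))
                lo = max(0, locus - spec.cluster_radius)
                hi = min(spec.genome_length - ln, locus + spec.cluster_radius)
                if hi <= lo:
                    continue
                s = int(rng.integers(lo, hi))
            else:
                s = int(rng.integers(0, spec.genome_length - ln))
            if not overlaps(s, s + ln):
                occupied.append((s, s + ln))
                starts[gi] = s
                break
        else:
            raise InvalidParameterError("could not place genes without overlap")
    df = pd.DataFrame(
        {
            "chrom": spec.chrom,
            "start": starts,
            "end": starts + lengths,
            "gene_id": [f"gene{i}" for i in range(spec.n_genes)],
            "repair": [i < spec.n_repair for i in range(spec.n_genes)],
        }
    ).sort_values("start").reset_index(drop=True)
    return df
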