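"""Randomization test for DNA-repair-gene enrichment near candidate loci.

Genes cluster on the genome by function, so a naive annotation-enrichment
test over the genes near candidate loci is biased. The unbiased test here
draws the same number of loci at random from the callable portion of the
genome, counts the distinct repair-flagged genes within a fixed radius of
any drawn locus, and compares the null distribution of that count with the
observed count; the empirical p-value is the plain proportion of draws
matching or exceeding the observation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "EnrichmentSetup",
    "genes_near_loci",
    "randomization_test",
    "read_bed",
]

log = logging.getLogger(__name__)

Interval = tuple[str, int, int]  # chrom, start, end; 0-based half-open


def read_bed(path, gene_bed: bool = False) -> pd.DataFrame:
    """Read a BED file (0-based half-open). With ``gene_bed=True``, the 4th
    column is the gene id and the 5th a 0/1 repair flag."""
    names = ["chrom", "start", "end"]
    if gene_bed:
        names += ["gene_id", "repair"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=names, usecols=range(len(names)), dtype={0: str})
    if gene_bed:
        df["repair"] = df["repair"].astype(int).astype(bool)
    return df


@dataclass(frozen=True)
class EnrichmentSetup:
    """Inputs for the randomization test."""

    candidate_loci: Sequence[Interval]
    genes: pd.DataFrame  # columns: chrom, start, end, gene_id, repair
    callable_regions: Sequence[Interval]
    radius: int = 100_000
    n_loci: int | None = None  # default: number of candidate loci
    reps: int = 100_000
    seed: int = 0
    resolved_n_loci: int = field(init=False)

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise InvalidParameterError("reps must be >= 1")
        if self.radius < 0:
            raise InvalidParameterError("radius must be >= 0")
        if not list(self.callable_regions):
            raise InvalidParameterError("callable regions must be non-empty")
        n = self.n_loci if self.n_loci is not None else len(list(self.candidate_loci))
        if n < 1:
            raise InvalidParameterError("n_loci must be >= 1")
        object.__setattr__(self, "resolved_n_loci", n)


def genes_near_loci(
    loci: Sequence[Interval], genes: pd.DataFrame, radius: int
) -> int:
    """Count distinct repair-flagged genes whose interval overlaps any locus
    interval expanded by ``radius`` on both sides. Each gene counts once no
    matter how many loci are near it."""
    flagged = genes[genes["repair"]]
    if flagged.empty:
        return 0
    loci = list(loci)
    gene_chroms = set(flagged["chrom"])
    locus_chroms = {c for c, _, _ in loci}
    if loci and not (gene_chroms & locus_chroms):
        log.warning(
            "no chromosome shared between loci (%s) and genes (%s)",
            sorted(locus_chroms), sorted(gene_chroms),
        )
    hit = np.zeros(len(flagged), dtype=bool)
    gc = flagged["chrom"].to_numpy()
    gs = flagged["start"].to_numpy()
    ge = flagged["end"].to_numpy()
    for chrom, start, end in loci:
        same = gc == chrom
        # locus expanded by radius overlaps gene iff gene_end > start-radius
        # and gene_start < end+radius (half-open intervals)
        hit |= same & (ge > start - radius) & (gs < end + radius)
    return int(hit.sum())


def _callable_space(regions: Sequence[Interval]):
    regions = list(regions)
    chroms = [c for c, _, _ in regions]
    starts = np.array([s for _, s, _ in regions], dtype=np.int64)
    ends = np.array([e for _, _, e in regions], dtype=np.int64)
    lens = ends - starts
    if np.any(lens <= 0):
        raise InvalidParameterError("callable regions must have positive length")
    cum = np.concatenate([[0], np.cumsum(lens)])
    return chroms, starts, cum


def randomization_test(setup: EnrichmentSetup) -> dict:
    """Empirical enrichment test.

    Each replicate draws ``n_loci`` point loci uniformly from the
    (length-weighted) callable space, expands them by ``radius`` and counts
    distinct repair-flagged genes; the p-value is the plain proportion of
    replicates with a count >= the observed count (a +1-corrected value is
    also reported).
    """
    observed = genes_near_loci(setup.candidate_loci, setup.genes, setup.radius)
    _warn_loci_outside(setup)
    chroms, starts, cum = _callable_space(setup.callable_regions)
    total = int(cum[-1])
    rng = np.random.default_rng(setup.seed)
    n_loci, reps = setup.resolved_n_loci, setup.reps

    draws = rng.integers(0, total, size=(reps, n_loci))
    reg_idx = np.searchsorted(cum, draws, side="right") - 1
    pos = starts[reg_idx] + (draws - cum[reg_idx])

    flagged = setup.genes[setup.genes["repair"]]
    null_counts = np.zeros(reps, dtype=np.int64)
    if not flagged.empty:
        rep_ids = np.repeat(np.arange(reps), n_loci)
        flat_chrom = np.asarray(chroms)[reg_idx.reshape(-1)]
        flat_pos = pos.reshape(-1)
        pair_rows = []
        for gi, (_, gene) in enumerate(flagged.iterrows()):
            mask = (
                (flat_chrom == gene["chrom"])
                & (flat_pos >= gene["start"] - setup.radius)
                & (flat_pos < gene["end"] + setup.radius)
            )
            if mask.any():
                pair_rows.append(rep_ids[mask] * len(flagged) + gi)
        if pair_rows:
            pairs = np.unique(np.concatenate(pair_rows))
            reps_hit, counts = np.unique(pairs // len(flagged), return_counts=True)
            null_counts[reps_hit] = counts

    n_ge = int((null_counts >= observed).sum())
    return {
        "observed": observed,
        "null_mean": float(null_counts.mean()),
        "null_q95": float(np.percentile(null_counts, 95)),
        "null_counts": null_counts,
        "p": n_ge / reps,
        "p_plus1": (n_ge + 1) / (reps + 1),
    }


def _warn_loci_outside(setup: EnrichmentSetup) -> None:
    for chrom, start, end in setup.candidate_loci:
        inside = any(
            c == chrom and s <= start and end <= e
            for c, s, e in setup.callable_regions
        )
        if not inside:
            log.warning("candidate locus %s:%d-%d lies outside the callable regions",
                        chrom, start, end)
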