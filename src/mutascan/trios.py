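"""Trio validation of candidate mutator loci.

If a mutator allele is still active on a highly derived haplotype, parents
carrying that haplotype should transmit more de novo mutations. Parents
are classified by copies (0/1/2) of the highly derived haplotype at a
locus — from per-haplotype derived counts when phasing is available, or
from per-individual counts (bimodal/trimodal) otherwise — and offspring
de novo counts are regressed on copy number with a robust (Huber
M-estimation) linear model. Significance is assessed two ways: the upper
tail of the slope t-statistic, and a permutation test that shuffles the
de novo counts across records while keeping covariates attached to their
records. Cohorts and parental sexes are never pooled, and a test requires
at least five carrier parents; Bonferroni correction uses the number of
tests actually performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    InvalidParameterError,
    NoHDClassError,
    TestNotApplicableError,
)

__all__ = [
    "TrioRecord",
    "TrioTestConfig",
    "classify_phased",
    "classify_unphased",
    "robust_association",
    "permutation_test",
    "run_trio_battery",
]


@dataclass(frozen=True)
class TrioRecord:
    """One parent of one trio: highly-derived-haplotype copies, the
    offspring's de novo mutation count, and optionally the parent's age at
    conception."""

    family_id: str
    parent_sex: str  # "paternal" | "maternal"
    hd_copies: int
    dnm_count: int
    parent_age: float | None = None

    def __post_init__(self) -> None:
        if self.hd_copies not in (0, 1, 2):
            raise InvalidParameterError("hd_copies must be 0, 1 or 2")
        if self.dnm_count < 0:
            raise InvalidParameterError("dnm_count must be >= 0")
        if self.parent_sex not in ("paternal", "maternal"):
            raise InvalidParameterError("parent_sex must be 'paternal' or 'maternal'")


@dataclass(frozen=True)
class TrioTestConfig:
    n_perm: int = 10_000
    min_carriers: int = 5
    seed: int = 0
    include_age_covariate: bool = False

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise InvalidParameterError("n_perm must be >= 1")
        if self.min_carriers < 1:
            raise InvalidParameterError("min_carriers must be >= 1")


# ---------------------------------------------------------------------------
# Haplotype classification


def classify_phased(
    counts: np.ndarray, threshold: float | None = None
) -> tuple[np.ndarray, float]:
    """Flag highly derived haplotypes from per-haplotype derived counts.

    Without an explicit threshold, the threshold is the midpoint of the
    largest gap between consecutive sorted counts lying above the median
    (a deterministic stand-in for choosing the visually best separation).
    A haplotype is highly derived iff its count exceeds the threshold.

    Returns (boolean flags, threshold used). Raises NoHDClassError when no
    gap wider than 1 exists above the median.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise InvalidParameterError("counts must be >= 0")
    if threshold is None:
        threshold = _largest_gap_threshold(counts)
    return counts > threshold, float(threshold)


def _largest_gap_threshold(counts: np.ndarray, min_gap: float = 1.0) -> float:
    srt = np.sort(counts)
    med = np.median(srt)
    gaps = np.diff(srt)
    # consider gaps whose lower edge is at or above the median
    eligible = np.flatnonzero((srt[:-1] >= med) & (gaps > min_gap))
    if eligible.size == 0:
        raise NoHDClassError("no separable highly derived class above the median")
    best = eligible[np.argmax(gaps[eligible])]
    return float(0.5 * (srt[best] + srt[best + 1]))


def hd_copies_phased(
    counts_pair: np.ndarray, threshold: float | None = None
) -> tuple[np.ndarray, float]:
    """Per-parent copy numbers from per-haplotype counts arranged as
    (n_parents, 2)."""
    counts_pair = np.asarray(counts_pair, dtype=float)
    flags, thr = classify_phased(counts_pair.reshape(-1), threshold)
    return flags.reshape(counts_pair.shape).sum(axis=1).astype(int), thr


def classify_unphased(
    counts: np.ndarray, thresholds: tuple[float, ...] | None = None
) -> tuple[np.ndarray, tuple[float, ...]]:
    """Copy numbers (0/1/2) from per-individual derived counts.

    The distribution of per-individual counts is bimodal when highly derived
    haplotypes are rare (0 vs 1 copy) and trimodal at higher frequency
    (0/1/2). One or two thresholds are placed at the largest inter-mode
    gaps; a gap qualifies when wider than max(1, 25% of the count range).
    Raises NoHDClassError for an effectively unimodal distribution.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise InvalidParameterError("counts must be >= 0")
    if thresholds is None:
        srt = np.sort(counts)
        gaps = np.diff(srt)
        span = srt[-1] - srt[0]
        min_gap = max(1.0, 0.25 * span)
        qualifying = np.flatnonzero(gaps > min_gap)
        if qualifying.size == 0:
            raise NoHDClassError("count distribution is unimodal")
        order = qualifying[np.argsort(gaps[qualifying])[::-1]][:2]
        thresholds = tuple(
            sorted(float(0.5 * (srt[i] + srt[i + 1])) for i in order)
        )
    copies = np.zeros(counts.size, dtype=int)
    for thr in thresholds:
        copies += (counts > thr).astype(int)
    return copies, tuple(thresholds)


# ---------------------------------------------------------------------------
# Association tests


def _design(records: list[TrioRecord], include_age: bool) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([r.dnm_count for r in records], dtype=float)
    cols = [np.ones(len(records)), np.array([r.hd_copies for r in records], float)]
    if include_age:
        ages = [r.parent_age for r in records]
        if any(a is None for a in ages):
            raise InvalidParameterError("age covariate requested but ages missing")
        cols.append(np.array(ages, dtype=float))
    return np.column_stack(cols), y


def _rlm_t(X: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Huber M-estimation fit; returns (slope coef, slope t-stat, df_resid)."""
    res = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345)).fit(scale_est="mad")
    return float(res.params[1]), float(res.tvalues[1]), int(res.df_resid)


def robust_association(
    records: list[TrioRecord], cfg: TrioTestConfig | None = None
) -> dict:
    """Robust linear regression of de novo count on highly-derived-haplotype
    copies (plus parental age when configured).

    Returns dict with ``coef``, ``t``, ``p_t`` (one-sided upper tail of the
    slope t-statistic at residual df) and ``n_carriers``. Raises
    TestNotApplicableError when fewer than ``min_carriers`` records carry a
    highly derived haplotype (reported as NA in tables).
    """
    cfg = cfg or TrioTestConfig()
    n_car = sum(1 for r in records if r.hd_copies >= 1)
    n_params = 3 if cfg.include_age_covariate else 2
    if n_car < cfg.min_carriers:
        raise TestNotApplicableError(
            f"only {n_car} carrier parents (< {cfg.min_carriers})"
        )
    if len(records) < n_params + 3:
        raise TestNotApplicableError("too few records for the regression")
    X, y = _design(records, cfg.include_age_covariate)
    coef, t, df = _rlm_t(X, y)
    p_t = float(stats.t.sf(t, df))
    return {"coef": coef, "t": t, "p_t": p_t, "n_carriers": n_car, "df": df}


def permutation_test(
    records: list[TrioRecord], cfg: TrioTestConfig | None = None
) -> dict:
    """Permutation p-value for the robust-regression slope.

    The de novo counts are permuted across records ``n_perm`` times (the
    covariates stay attached to their records) and the slope t-statistic is
    recomputed; ``p_perm`` is the plain proportion of permuted t-statistics
    greater than or equal to the observed one (0 is attainable). A
    +1-corrected value ``p_perm_plus1`` is reported alongside.
    """
    cfg = cfg or TrioTestConfig()
    obs = robust_association(records, cfg)
    X, y = _design(records, cfg.include_age_covariate)
    rng = np.random.default_rng(cfg.seed)
    n_ge = 0
    for _ in range(cfg.n_perm):
        y_perm = rng.permutation(y)
        _, t_perm, _ = _rlm_t(X, y_perm)
        if t_perm >= obs["t"]:
            n_ge += 1
    obs["p_perm"] = n_ge / cfg.n_perm
    obs["p_perm_plus1"] = (n_ge + 1) / (cfg.n_perm + 1)
    return obs


def run_trio_battery(
    cells: dict[tuple[str, str, str], list[TrioRecord]],
    cfg: TrioTestConfig | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the association tests over (locus, cohort, parent sex) cells.

    Each cell gets its own test (cohorts and sexes never pool records);
    cells failing the carrier minimum are reported NA. The Bonferroni factor
    is the number of tests actually performed, and ``significant`` flags
    cells with Bonferroni-adjusted permutation p below ``alpha``.
    """
    cfg = cfg or TrioTestConfig()
    rows = []
    for (locus, cohort, sex), records in cells.items():
        try:
            res = permutation_test(records, cfg)
            rows.append(
                {
                    "locus": locus,
                    "cohort": cohort,
                    "parent_sex": sex,
                    "n_records": len(records),
                    "n_carriers": res["n_carriers"],
                    "coef": res["coef"],
                    "t": res["t"],
                    "p_t": res["p_t"],
                    "p_perm": res["p_perm"],
                    "performed": True,
                }
            )
        except TestNotApplicableError:
            rows.append(
                {
                    "locus": locus,
                    "cohort": cohort,
                    "parent_sex": sex,
                    "n_records": len(records),
                    "n_carriers": sum(1 for r in records if r.hd_copies >= 1),
                    "coef": np.nan,
                    "t": np.nan,
                    "p_t": np.nan,
                    "p_perm": np.nan,
                    "performed": False,
                }
            )
    columns = [
        "locus", "cohort", "parent_sex", "n_records", "n_carriers",
        "coef", "t", "p_t", "p_perm", "performed",
    ]
    df = pd.DataFrame(rows, columns=columns)
    n_tests = int(df["performed"].sum())
    df.attrs["bonferroni_factor"] = n_tests
    df["p_t_bonferroni"] = np.where(
        df["performed"], np.minimum(df["p_t"] * max(n_tests, 1), 1.0), np.nan
    )
    df["p_perm_bonferroni"] = np.where(
        df["performed"], np.minimum(df["p_perm"] * max(n_tests, 1), 1.0), np.nan
    )
    df["significant"] = df["performed"] & (df["p_perm_bonferroni"] < alpha)
    return df
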