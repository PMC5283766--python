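"""Sliding-window genome scan for mutator-locus signatures.

For every haplotype the derived-allele count is accumulated in overlapping
windows (default 10 kb, 1 kb step). Each window is summarised by the
interquartile mean (IQM, the 25% trimmed mean) over haplotypes and by the
maximum over haplotypes. Ordinary least squares of the maximum on the IQM
across all windows defines a regression line; the scan statistic M of a
window is the residual of its maximum from that line. A low-frequency
mutator allele inflates the maximum but not the trimmed mean, so candidate
loci are windows with a large positive M. Windows whose IQM exceeds the
75th percentile (diversifying selection inflates both summaries) and
windows where more than 5% of SNPs fail a Hardy-Weinberg chi-square test
within some population (likely genotyping artefacts) are excluded from
candidate reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from scipy import stats

from .errors import (
    InsufficientHaplotypesError,
    InvalidParameterError,
    PhasingRequiredError,
    SingularFitError,
)
from .simulate import HaplotypeSample

__all__ = [
    "ScanConfig",
    "WindowStats",
    "read_derived_matrix",
    "window_counts",
    "iqm_and_max",
    "fit_max_vs_iqm",
    "m_statistic",
    "hwe_snp_test",
    "hwe_window_filter",
    "rank_candidates",
    "scan_sample",
]

_BASES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class ScanConfig:
    window_size: int = 10_000
    step: int = 1_000
    iqm_exclusion_percentile: float = 75.0
    hwe_alpha: float = 0.05
    hwe_max_fraction: float = 0.05
    residual_threshold: float = 18.0
    mode: str = "combined"  # "combined" | "per-population"

    def __post_init__(self) -> None:
        if not self.window_size >= self.step > 0:
            raise InvalidParameterError("require window_size >= step > 0")
        if not 0 < self.iqm_exclusion_percentile < 100:
            raise InvalidParameterError("percentile must lie in (0, 100)")
        for frac in (self.hwe_alpha, self.hwe_max_fraction):
            if not 0 <= frac <= 1:
                raise InvalidParameterError("fractions must lie in [0, 1]")
        if self.mode not in ("combined", "per-population"):
            raise InvalidParameterError("mode must be 'combined' or 'per-population'")


@dataclass
class WindowStats:
    """Per-window scan summary; ``m = max - fitted`` once a fit is attached."""

    chrom: str
    start: int
    iqm: float
    max: float
    n_snps: int
    fitted: float = float("nan")
    m: float = float("nan")
    hwe_fail_fraction: float = 0.0
    excluded_reason: str = "none"


def read_derived_matrix(
    vcf_path, panel_path=None, population_filter: str | None = None
) -> HaplotypeSample:
    """Read a phased VCF with INFO/AA annotation into a derived-allele matrix.

    Sites are kept only when biallelic SNPs with a high-confidence ancestral
    allele: AA must be a single uppercase base equal to REF or ALT (the
    1000 Genomes convention encodes low confidence as lowercase). Derived
    calls are alleles differing from AA. Haplotypes are ordered
    (sample1-hapA, sample1-hapB, sample2-hapA, ...).

    ``panel_path`` is a TSV with columns (sample, pop, super_pop);
    ``population_filter`` keeps only samples from one population.
    """
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    if panel_path is not None:
        panel = pd.read_csv(panel_path, sep="\t", dtype=str)
        pop_of = dict(zip(panel["sample"], panel["pop"]))
    else:
        pop_of = {s: "pop0" for s in samples}
    keep_idx = [
        i
        for i, s in enumerate(samples)
        if population_filter is None or pop_of.get(s) == population_filter
    ]
    if not keep_idx:
        raise InvalidParameterError("no samples left after population filter")
    pops = np.repeat([pop_of.get(samples[i], "pop0") for i in keep_idx], 2)

    positions, cols = [], []
    skipped = {"multiallelic": 0, "not_snp": 0, "aa_low_confidence": 0,
               "aa_mismatch": 0}
    max_pos = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            skipped["not_snp"] += 1
            continue
        aa = var.INFO.get("AA")
        aa = (aa or "").split("|")[0].strip()
        if len(aa) != 1 or aa not in _BASES:  # lowercase/'.'/'-'/'N' etc.
            skipped["aa_low_confidence"] += 1
            continue
        if aa not in (ref, alt):
            skipped["aa_mismatch"] += 1
            continue
        gt = np.array(var.genotypes)  # (n_samples, 3): a, b, phased
        sel = gt[keep_idx]
        het = sel[:, 0] != sel[:, 1]
        if np.any(het & (sel[:, 2] == 0)):
            raise PhasingRequiredError(
                f"unphased heterozygous genotype at {var.CHROM}:{var.POS}"
            )
        alleles = sel[:, :2].reshape(-1)  # haplotype order hapA, hapB
        derived_allele = 1 if aa == ref else 0
        cols.append((alleles == derived_allele).astype(np.uint8))
        positions.append(var.POS - 1)  # to 0-based
        max_pos = max(max_pos, var.POS)
    length = None
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig") and "length=" in line:
            length = int(line.split("length=")[1].rstrip(">").split(",")[0])
            break
    if length is None:
        length = max_pos + 1
    calls = (
        np.stack(cols, axis=1)
        if cols
        else np.zeros((len(keep_idx) * 2, 0), dtype=np.uint8)
    )
    return HaplotypeSample(
        positions=np.array(positions, dtype=np.int64),
        calls=calls,
        length=length,
        carrier=None,
        population=pops,
        meta={"skipped": skipped, "vcf": str(vcf_path)},
    )


def window_starts(max_position: int, cfg: ScanConfig) -> np.ndarray:
    """Half-open window start coordinates: 0, step, ..., last <= max position."""
    if max_position < 0:
        return np.array([0], dtype=np.int64)
    return np.arange(0, max_position + 1, cfg.step, dtype=np.int64)


def window_counts(sample: HaplotypeSample, cfg: ScanConfig) -> tuple[np.ndarray, np.ndarray]:
    """Derived-allele counts per window per haplotype.

    Windows are half-open ``[start, start + window_size)`` anchored at 0.
    Returns (starts, counts) with counts of shape (n_windows, n_haplotypes).
    """
    pos = sample.positions
    max_pos = int(pos.max()) if pos.size else 0
    starts = window_starts(max_pos, cfg)
    # prefix sums over sites per haplotype for O(1) window sums
    prefix = np.zeros((pos.size + 1, sample.n_haplotypes), dtype=np.int64)
    if pos.size:
        np.cumsum(sample.calls.T, axis=0, out=prefix[1:])
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, starts + cfg.window_size, side="left")
    counts = prefix[hi] - prefix[lo]
    return starts, counts


def iqm_and_max(counts: Iterable[float]) -> tuple[float, float]:
    """Interquartile mean (drop floor(n/4) values from each end of the
    sorted counts, average the rest) and the maximum."""
    arr = np.sort(np.asarray(list(counts), dtype=float))
    n = arr.size
    if n < 4:
        raise InsufficientHaplotypesError("need at least 4 haplotypes for the IQM")
    k = n // 4
    return float(arr[k : n - k].mean()), float(arr[-1])


def fit_max_vs_iqm(windows: list[WindowStats]) -> tuple[float, float]:
    """OLS fit of window maximum on window IQM over ALL windows (before any
    exclusion). Returns (slope, intercept)."""
    iqm = np.array([w.iqm for w in windows], dtype=float)
    mx = np.array([w.max for w in windows], dtype=float)
    if len(windows) < 3 or np.unique(iqm).size < 2:
        raise SingularFitError("need >= 3 windows with distinct IQM values")
    res = stats.linregress(iqm, mx)
    return float(res.slope), float(res.intercept)


def m_statistic(window: WindowStats, fit: tuple[float, float]) -> float:
    """Residual of the window maximum from the regression line; positive
    above the line."""
    slope, intercept = fit
    return window.max - (intercept + slope * window.iqm)


def hwe_snp_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """1-df chi-square p-value for Hardy-Weinberg equilibrium of one SNP's
    diploid genotype counts (no continuity correction). Returns nan for
    monomorphic SNPs (test skipped)."""
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return float("nan")
    p = (2 * n_hom_ref + n_het) / (2.0 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return float("nan")
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _snp_hwe_failures(sample: HaplotypeSample, alpha: float) -> np.ndarray:
    """Per-site flag: SNP rejects HWE (p < alpha) in at least one population.

    Haplotypes (2i, 2i+1) form diploid i; populations are taken from the
    haplotype labels (constant within a diploid).
    """
    n_dip = sample.n_haplotypes // 2
    a = sample.calls[0 : 2 * n_dip : 2, :].astype(np.int16)
    b = sample.calls[1 : 2 * n_dip : 2, :].astype(np.int16)
    geno = a + b  # 0/1/2 derived copies per diploid per site
    pops = np.asarray(sample.population)[0 : 2 * n_dip : 2]
    fails = np.zeros(sample.n_sites, dtype=bool)
    for pop in np.unique(pops):
        sub = geno[pops == pop]
        n0 = (sub == 0).sum(axis=0).astype(float)
        n1 = (sub == 1).sum(axis=0).astype(float)
        n2 = (sub == 2).sum(axis=0).astype(float)
        n = n0 + n1 + n2
        with np.errstate(divide="ignore", invalid="ignore"):
            p = (2 * n0 + n1) / (2 * n)
            q = 1.0 - p
            poly = (p > 0) & (q > 0) & (n > 0)
            exp0, exp1, exp2 = n * p * p, 2 * n * p * q, n * q * q
            chi2 = (
                (n0 - exp0) ** 2 / exp0
                + (n1 - exp1) ** 2 / exp1
                + (n2 - exp2) ** 2 / exp2
            )
        pvals = stats.chi2.sf(chi2, df=1)
        fails |= poly & (pvals < alpha)
    return fails


def hwe_window_filter(
    sample: HaplotypeSample, starts: np.ndarray, cfg: ScanConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window HWE verdict.

    Returns (keep flags, fail fractions): a window is dropped when the
    fraction of its SNPs failing HWE in any population exceeds
    ``cfg.hwe_max_fraction`` (strict inequality)."""
    fails = _snp_hwe_failures(sample, cfg.hwe_alpha)
    pos = sample.positions
    frac = np.zeros(starts.size)
    for i, s in enumerate(starts):
        lo, hi = np.searchsorted(pos, [s, s + cfg.window_size], side="left")
        if hi > lo:
            frac[i] = fails[lo:hi].mean()
    return frac <= cfg.hwe_max_fraction, frac


def scan_sample(
    sample: HaplotypeSample,
    cfg: ScanConfig | None = None,
    chrom: str = "1",
    hwe: bool = True,
) -> pd.DataFrame:
    """Full scan of one sample: window stats, fit, M, exclusion flags.

    In ``per-population`` mode, counts and summaries are computed within each
    population and windows from all populations enter one common fit and
    ranking; in ``combined`` mode all haplotypes are pooled.
    """
    cfg = cfg or ScanConfig()
    groups: list[tuple[str, HaplotypeSample]] = []
    if cfg.mode == "per-population":
        pops = np.asarray(sample.population)
        for pop in np.unique(pops):
            mask = pops == pop
            sub = HaplotypeSample(
                positions=sample.positions,
                calls=sample.calls[mask],
                length=sample.length,
                population=pops[mask],
            )
            groups.append((pop, sub))
    else:
        groups.append(("all", sample))

    rows: list[WindowStats] = []
    extra: list[str] = []
    for label, sub in groups:
        starts, counts = window_counts(sub, cfg)
        if hwe:
            keep_hwe, frac = hwe_window_filter(sub, starts, cfg)
        else:
            keep_hwe = np.ones(starts.size, dtype=bool)
            frac = np.zeros(starts.size)
        pos = sub.positions
        for i, s in enumerate(starts):
            iqm, mx = iqm_and_max(counts[i])
            lo, hi = np.searchsorted(pos, [s, s + cfg.window_size], side="left")
            w = WindowStats(
                chrom=chrom,
                start=int(s),
                iqm=iqm,
                max=mx,
                n_snps=int(hi - lo),
                hwe_fail_fraction=float(frac[i]),
            )
            if not keep_hwe[i]:
                w.excluded_reason = "hwe"
            rows.append(w)
            extra.append(label)

    slope, intercept = fit_max_vs_iqm(rows)
    iqm_cut = float(np.percentile([w.iqm for w in rows], cfg.iqm_exclusion_percentile))
    for w in rows:
        w.fitted = intercept + slope * w.iqm
        w.m = m_statistic(w, (slope, intercept))
        if w.excluded_reason == "none" and w.iqm > iqm_cut:
            w.excluded_reason = "high_iqm"

    df = pd.DataFrame(
        {
            "chrom": [w.chrom for w in rows],
            "start": [w.start for w in rows],
            "end": [w.start + cfg.window_size for w in rows],
            "group": extra,
            "iqm": [w.iqm for w in rows],
            "max": [w.max for w in rows],
            "n_snps": [w.n_snps for w in rows],
            "fitted": [w.fitted for w in rows],
            "m": [w.m for w in rows],
            "hwe_fail_fraction": [w.hwe_fail_fraction for w in rows],
            "excluded_reason": [w.excluded_reason for w in rows],
        }
    )
    df.attrs["fit"] = (slope, intercept)
    df.attrs["iqm_cut"] = iqm_cut
    return df


def rank_candidates(windows: pd.DataFrame, cfg: ScanConfig | None = None) -> pd.DataFrame:
    """Candidate loci: windows surviving exclusions with M at or above the
    reporting threshold, merged into loci when within one window size of each
    other, each locus reported at its window of maximal M, sorted by M
    descending. Columns mirror the scan's per-window table."""
    cfg = cfg or ScanConfig()
    ok = windows[
        (windows["excluded_reason"] == "none")
        & (windows["m"] >= cfg.residual_threshold)
    ].copy()
    if ok.empty:
        return ok
    keys = ["chrom", "group"] if "group" in ok.columns else ["chrom"]
    out = []
    for _, grp in ok.groupby(keys):
        grp = grp.sort_values("start")
        best = None
        prev_start = None
        for _, row in grp.iterrows():
            if prev_start is not None and row["start"] - prev_start <= cfg.window_size:
                if row["m"] > best["m"]:
                    best = row
            else:
                if best is not None:
                    out.append(best)
                best = row
            prev_start = row["start"]
        if best is not None:
            out.append(best)
    res = pd.DataFrame(out).sort_values("m", ascending=False).reset_index(drop=True)
    return res
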