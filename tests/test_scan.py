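"""Hand-computed fixtures and properties for the sliding-window scan."""

import numpy as np
import pandas as pd
import pytest

from mutascan import scan as sc
from mutascan import synthetic as synth
from mutascan.errors import (
    InsufficientHaplotypesError,
    InvalidParameterError,
    PhasingRequiredError,
    SingularFitError,
)
from mutascan.simulate import HaplotypeSample, NullDemography, RegionSpec, simulate_null


def _sample(positions, calls, length=100_000, population=None):
    return HaplotypeSample(
        positions=np.asarray(positions, dtype=np.int64),
        calls=np.asarray(calls, dtype=np.uint8),
        length=length,
        population=population,
    )


# ---------------------------------------------------------------------------
# VCF reading


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1,length=100000>\n"
    '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral Allele">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS0\n"
)


def _write_vcf(tmp_path, body, name="t.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + body)
    return path


class TestReadDerivedMatrix:
    def test_ref_is_derived_when_aa_equals_alt(self, tmp_path):
        # REF=A ALT=G AA=G, GT=0|1 -> haplotype A carries REF = derived
        path = _write_vcf(tmp_path, "1\t100\t.\tA\tG\t.\tPASS\tAA=G\tGT\t0|1\n")
        s = sc.read_derived_matrix(path)
        assert s.positions.tolist() == [99]
        assert s.calls[:, 0].tolist() == [1, 0]

    def test_lowercase_aa_skipped(self, tmp_path):
        path = _write_vcf(tmp_path, "1\t100\t.\tA\tG\t.\tPASS\tAA=a\tGT\t0|1\n")
        s = sc.read_derived_matrix(path)
        assert s.n_sites == 0
        assert s.meta["skipped"]["aa_low_confidence"] == 1

    def test_multiallelic_skipped(self, tmp_path):
        path = _write_vcf(tmp_path, "1\t100\t.\tA\tG,T\t.\tPASS\tAA=A\tGT\t0|1\n")
        s = sc.read_derived_matrix(path)
        assert s.n_sites == 0
        assert s.meta["skipped"]["multiallelic"] == 1

    def test_aa_mismatch_skipped(self, tmp_path):
        path = _write_vcf(tmp_path, "1\t100\t.\tA\tG\t.\tPASS\tAA=T\tGT\t0|1\n")
        s = sc.read_derived_matrix(path)
        assert s.n_sites == 0
        assert s.meta["skipped"]["aa_mismatch"] == 1

    def test_indel_skipped(self, tmp_path):
        path = _write_vcf(tmp_path, "1\t100\t.\tAT\tG\t.\tPASS\tAA=G\tGT\t0|1\n")
        s = sc.read_derived_matrix(path)
        assert s.meta["skipped"]["not_snp"] == 1

    def test_unphased_het_raises(self, tmp_path):
        path = _write_vcf(tmp_path, "1\t100\t.\tA\tG\t.\tPASS\tAA=A\tGT\t0/1\n")
        with pytest.raises(PhasingRequiredError):
            sc.read_derived_matrix(path)

    def test_contig_length_used(self, tmp_path):
        path = _write_vcf(tmp_path, "1\t100\t.\tA\tG\t.\tPASS\tAA=A\tGT\t0|1\n")
        assert sc.read_derived_matrix(path).length == 100_000


# ---------------------------------------------------------------------------
# Window counting


class TestWindowCounts:
    def test_hand_count_half_open(self):
        s = _sample([500, 9_999], np.ones((1, 2)), length=20_000)
        starts, counts = sc.window_counts(s, sc.ScanConfig())
        by_start = dict(zip(starts.tolist(), counts[:, 0].tolist()))
        assert by_start[0] == 2  # [0, 10000) holds both
        assert by_start[1000] == 1  # [1000, 11000) holds only 9999
        assert by_start[9000] == 1

    def test_no_sites_all_zero(self):
        s = _sample([], np.zeros((3, 0)), length=20_000)
        _, counts = sc.window_counts(s, sc.ScanConfig())
        assert counts.sum() == 0

    def test_translation_by_step(self):
        cfg = sc.ScanConfig()
        pos = np.array([1_500, 4_200, 8_000])
        a = _sample(pos, np.ones((1, 3)), length=40_000)
        b = _sample(pos + cfg.step, np.ones((1, 3)), length=40_000)
        sa, ca = sc.window_counts(a, cfg)
        sb, cb = sc.window_counts(b, cfg)
        # counts shift by exactly one window
        n = min(ca.shape[0], cb.shape[0] - 1)
        assert np.array_equal(ca[:n], cb[1 : n + 1])


# ---------------------------------------------------------------------------
# IQM / max, OLS fit, M


class TestIqmAndMax:
    def test_hand_case(self):
        assert sc.iqm_and_max([0, 1, 2, 3, 4, 5, 6, 7]) == (3.5, 7.0)

    def test_constant(self):
        assert sc.iqm_and_max([5, 5, 5, 5]) == (5.0, 5.0)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 50, size=17)
        assert sc.iqm_and_max(x) == sc.iqm_and_max(rng.permutation(x))

    def test_too_few(self):
        with pytest.raises(InsufficientHaplotypesError):
            sc.iqm_and_max([1, 2, 3])


def _windows(pairs):
    return [
        sc.WindowStats(chrom="1", start=i * 1000, iqm=float(a), max=float(b), n_snps=0)
        for i, (a, b) in enumerate(pairs)
    ]


class TestFitAndM:
    def test_perfect_fit(self):
        slope, intercept = sc.fit_max_vs_iqm(_windows([(0, 1), (1, 3), (2, 5)]))
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)

    def test_normal_equation_oracle(self):
        pairs = [(0, 1), (1, 3), (2, 5), (1, 11)]
        slope, intercept = sc.fit_max_vs_iqm(_windows(pairs))
        x = np.array([p[0] for p in pairs], float)
        y = np.array([p[1] for p in pairs], float)
        # brute-force grid refinement around the closed form
        best = min(
            (
                (((y - (b + a * x)) ** 2).sum(), a, b)
                for a in np.linspace(-10, 10, 2001)
                for b in np.linspace(-10, 10, 401)
            )
        )
        assert slope == pytest.approx(best[1], abs=2e-2)
        assert intercept == pytest.approx(best[2], abs=1e-1)
        # residuals of the OLS fit sum to zero
        assert (y - (intercept + slope * x)).sum() == pytest.approx(0.0, abs=1e-8)

    def test_duplication_invariance(self):
        pairs = [(0, 1), (1, 3), (2, 5), (1, 11)]
        assert sc.fit_max_vs_iqm(_windows(pairs)) == pytest.approx(
            sc.fit_max_vs_iqm(_windows(pairs + pairs))
        )

    def test_singular(self):
        with pytest.raises(SingularFitError):
            sc.fit_max_vs_iqm(_windows([(1, 2), (1, 3), (1, 4)]))

    def test_m_statistic_hand(self):
        w = sc.WindowStats(chrom="1", start=0, iqm=15.4, max=106.0, n_snps=0)
        assert sc.m_statistic(w, (2.0, 1.0)) == pytest.approx(106 - (1 + 2 * 15.4))
        on_line = sc.WindowStats(chrom="1", start=0, iqm=3.0, max=7.0, n_snps=0)
        assert sc.m_statistic(on_line, (2.0, 1.0)) == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# Hardy-Weinberg filter


class TestHwe:
    def test_exact_hwe_passes(self):
        assert sc.hwe_snp_test(25, 50, 25) == pytest.approx(1.0)

    def test_no_hets_chi2_100(self):
        from scipy import stats

        p = sc.hwe_snp_test(50, 0, 50)
        assert p == pytest.approx(float(stats.chi2.sf(100.0, 1)))
        assert p < 0.05

    def test_monomorphic_nan(self):
        assert np.isnan(sc.hwe_snp_test(100, 0, 0))

    def _bulk_sample(self, n_fail, n_pass, n_dip=40):
        """n_fail sites where every diploid is het (rejects HWE), n_pass
        sites in exact HWE proportions."""
        cols = []
        fail_col = np.tile([1, 0], n_dip)  # every diploid 1|0 het
        q = n_dip // 4
        # q hom-derived, 2q het, q hom-ancestral diploids: exact HWE at p=0.5
        pass_col = np.concatenate(
            [np.ones(2 * q, dtype=int), np.tile([1, 0], 2 * q), np.zeros(2 * q)]
        )
        for _ in range(n_fail):
            cols.append(fail_col)
        for _ in range(n_pass):
            cols.append(pass_col)
        calls = np.stack(cols, axis=1)
        positions = np.arange(len(cols)) * 10 + 5
        return _sample(positions, calls, length=10_000)

    def test_fail_and_pass_flags(self):
        s = self._bulk_sample(n_fail=6, n_pass=94)
        cfg = sc.ScanConfig()
        keep, frac = sc.hwe_window_filter(s, np.array([0]), cfg)
        assert frac[0] == pytest.approx(0.06)
        assert not keep[0]

    def test_strict_inequality_rule(self):
        s = self._bulk_sample(n_fail=5, n_pass=95)
        cfg = sc.ScanConfig()
        keep, frac = sc.hwe_window_filter(s, np.array([0]), cfg)
        assert frac[0] == pytest.approx(0.05)
        assert keep[0]  # 0.05 is not > 0.05


# ---------------------------------------------------------------------------
# Full scan and ranking


class TestScanSample:
    def _neutral(self, seed=11):
        return simulate_null(
            NullDemography(sample_size=60),
            RegionSpec(length=100_000, locus_position=50_000),
            seed=seed,
        )

    def test_m_identity_and_residual_sum(self):
        df = sc.scan_sample(self._neutral(), sc.ScanConfig())
        assert np.allclose(df["m"], df["max"] - df["fitted"])
        assert df["m"].sum() == pytest.approx(0.0, abs=1e-6)
        assert (df["iqm"] <= df["max"]).all()

    def test_haplotype_order_invariance(self):
        s = self._neutral()
        rng = np.random.default_rng(3)
        perm = rng.permutation(s.n_haplotypes)
        shuffled = HaplotypeSample(
            positions=s.positions,
            calls=s.calls[perm],
            length=s.length,
            population=np.asarray(s.population)[perm],
        )
        a = sc.scan_sample(s, sc.ScanConfig(), hwe=False)
        b = sc.scan_sample(shuffled, sc.ScanConfig(), hwe=False)
        assert np.allclose(a["m"], b["m"])

    def test_spiked_window_ranks_first(self):
        base = self._neutral(seed=21)
        spiked = synth.spike_scan_fixture(
            base, k=5, extra=30, window=(45_000, 55_000), seed=5
        )
        df = sc.scan_sample(spiked, sc.ScanConfig())
        cands = sc.rank_candidates(df, sc.ScanConfig())
        assert len(cands) >= 1
        top = cands.iloc[0]
        assert top["start"] < 55_000 and top["end"] > 45_000

    def test_per_population_mode_groups(self):
        s = simulate_null(
            NullDemography(mode="split", n_pops=5, sample_size=50),
            RegionSpec(length=50_000, locus_position=25_000),
            seed=9,
        )
        df = sc.scan_sample(s, sc.ScanConfig(mode="per-population"), hwe=False)
        assert set(df["group"]) == {f"pop{i}" for i in range(5)}

    def test_invalid_config(self):
        with pytest.raises(InvalidParameterError):
            sc.ScanConfig(window_size=100, step=1000)


class TestRankCandidates:
    def _df(self, rows):
        df = pd.DataFrame(
            rows, columns=["chrom", "start", "m", "excluded_reason", "group"]
        )
        df["end"] = df["start"] + 10_000
        return df

    def test_merge_within_window_size(self):
        df = self._df(
            [
                ("1", 0, 20.0, "none", "all"),
                ("1", 5_000, 25.0, "none", "all"),
                ("1", 9_000, 19.0, "none", "all"),
                ("1", 40_000, 30.0, "none", "all"),
            ]
        )
        out = sc.rank_candidates(df, sc.ScanConfig())
        assert len(out) == 2
        assert out.iloc[0]["start"] == 40_000  # sorted by m desc
        assert out.iloc[1]["start"] == 5_000  # merged locus kept at max m

    def test_exclusions_and_threshold(self):
        df = self._df(
            [
                ("1", 0, 50.0, "high_iqm", "all"),
                ("1", 30_000, 50.0, "hwe", "all"),
                ("1", 60_000, 17.9, "none", "all"),
            ]
        )
        assert sc.rank_candidates(df, sc.ScanConfig()).empty
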