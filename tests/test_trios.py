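"""Trio-validation tests: classification fixtures, an exhaustive permutation
oracle, invariances, and battery bookkeeping."""

import itertools

import numpy as np
import pytest
from scipy import stats

from mutascan import errors, trios
from mutascan.errors import InvalidParameterError, NoHDClassError
from mutascan.synthetic import TrioCohortSpec, generate_trio_cohort


# ---------------------------------------------------------------------------
# Haplotype classification


class TestClassifyPhased:
    def test_hand_case(self):
        flags, thr = trios.classify_phased(np.array([5, 6, 7, 40, 41]))
        assert thr == pytest.approx(23.5)
        assert flags.tolist() == [False, False, False, True, True]

    def test_constant_counts_raise(self):
        with pytest.raises(NoHDClassError):
            trios.classify_phased(np.array([10, 10, 10, 10]))

    def test_explicit_threshold(self):
        flags, thr = trios.classify_phased(np.array([5, 15]), threshold=10)
        assert thr == 10
        assert flags.tolist() == [False, True]

    def test_negative_counts_raise(self):
        with pytest.raises(InvalidParameterError):
            trios.classify_phased(np.array([-1, 5]))

    def test_copies_from_pairs(self):
        pairs = np.array([[5, 6], [7, 40], [41, 5], [6, 7]])
        copies, thr = trios.hd_copies_phased(pairs)
        assert thr == pytest.approx(23.5)
        assert copies.tolist() == [0, 1, 1, 0]


class TestClassifyUnphased:
    def test_bimodal(self):
        rng = np.random.default_rng(0)
        counts = np.concatenate(
            [rng.normal(10, 1, 40), rng.normal(45, 1, 10)]
        ).clip(min=0)
        copies, thrs = trios.classify_unphased(counts)
        assert len(thrs) == 1
        assert set(copies[:40]) == {0} and set(copies[40:]) == {1}

    def test_trimodal(self):
        rng = np.random.default_rng(1)
        counts = np.concatenate(
            [rng.normal(10, 1, 30), rng.normal(45, 1, 12), rng.normal(80, 1, 6)]
        ).clip(min=0)
        copies, thrs = trios.classify_unphased(counts)
        assert len(thrs) == 2
        assert set(copies[:30]) == {0}
        assert set(copies[30:42]) == {1}
        assert set(copies[42:]) == {2}

    def test_unimodal_raises(self):
        rng = np.random.default_rng(2)
        with pytest.raises(NoHDClassError):
            trios.classify_unphased(rng.normal(10, 0.2, 50).clip(min=0))


# ---------------------------------------------------------------------------
# Association tests


def _records(copies, counts, ages=None):
    return [
        trios.TrioRecord(
            family_id=f"f{i}",
            parent_sex="paternal",
            hd_copies=int(c),
            dnm_count=int(d),
            parent_age=None if ages is None else float(ages[i]),
        )
        for i, (c, d) in enumerate(zip(copies, counts))
    ]


class TestRobustAssociation:
    def test_min_carriers_na(self):
        recs = _records([0] * 17 + [1] * 3, list(range(20)))
        with pytest.raises(errors.TestNotApplicableError):
            trios.robust_association(recs, trios.TrioTestConfig())

    def test_positive_effect_detected(self):
        rng = np.random.default_rng(7)
        copies = np.array([0] * 40 + [1] * 10)
        counts = rng.poisson(45 + 15 * copies)
        res = trios.robust_association(_records(copies, counts))
        assert res["coef"] > 0
        assert res["p_t"] < 0.05
        assert res["n_carriers"] == 10

    def test_location_invariance(self):
        rng = np.random.default_rng(8)
        copies = np.array([0] * 30 + [1] * 10)
        counts = rng.poisson(45, size=40)
        a = trios.robust_association(_records(copies, counts))
        b = trios.robust_association(_records(copies, counts + 100))
        assert a["t"] == pytest.approx(b["t"], rel=1e-8)
        assert a["p_t"] == pytest.approx(b["p_t"], rel=1e-8)

    def test_age_covariate_required(self):
        copies = [0] * 10 + [1] * 6
        counts = list(range(16))
        cfg = trios.TrioTestConfig(include_age_covariate=True)
        with pytest.raises(InvalidParameterError):
            trios.robust_association(_records(copies, counts), cfg)

    def test_p_t_matches_t_distribution(self):
        rng = np.random.default_rng(9)
        copies = np.array([0] * 30 + [1] * 10)
        counts = rng.poisson(45, size=40)
        res = trios.robust_association(_records(copies, counts))
        assert res["p_t"] == pytest.approx(float(stats.t.sf(res["t"], res["df"])))


class TestPermutationTest:
    def test_enumeration_oracle(self):
        """Monte-Carlo p_perm matches the exhaustive all-permutations
        proportion within 3 binomial SEs."""
        copies = [0, 1, 1, 1, 2, 2]
        counts = [40, 44, 55, 47, 61, 58]
        recs = _records(copies, counts)
        X = np.column_stack([np.ones(6), np.array(copies, float)])
        y = np.array(counts, float)
        t_obs = trios._rlm_t(X, y)[1]
        exact = np.mean(
            [
                trios._rlm_t(X, np.array(p, float))[1] >= t_obs
                for p in itertools.permutations(counts)
            ]
        )
        cfg = trios.TrioTestConfig(n_perm=1500, seed=5)
        res = trios.permutation_test(recs, cfg)
        se = np.sqrt(exact * (1 - exact) / cfg.n_perm)
        assert abs(res["p_perm"] - exact) <= 3 * se + 1e-12
        assert res["p_perm_plus1"] == pytest.approx(
            (res["p_perm"] * cfg.n_perm + 1) / (cfg.n_perm + 1)
        )

    def test_zero_attainable(self):
        # overwhelming effect: observed t exceeds every permuted t
        copies = [0] * 10 + [1] * 10
        counts = [10] * 10 + [1000] * 10
        res = trios.permutation_test(
            _records(copies, counts), trios.TrioTestConfig(n_perm=300, seed=0)
        )
        assert res["p_perm"] == 0.0

    def test_seed_reproducible(self):
        rng = np.random.default_rng(11)
        copies = np.array([0] * 20 + [1] * 8)
        counts = rng.poisson(45, size=28)
        cfg = trios.TrioTestConfig(n_perm=200, seed=42)
        a = trios.permutation_test(_records(copies, counts), cfg)
        b = trios.permutation_test(_records(copies, counts), cfg)
        assert a["p_perm"] == b["p_perm"]

    def test_power_monotone_in_effect(self):
        """Rejection frequency increases with the synthetic effect delta."""
        power = {}
        for delta in (0, 5, 15):
            hits = 0
            for seed in range(12):
                spec = TrioCohortSpec(
                    n_trios=60, carrier_freq=0.3, lambda0=45, delta=delta, seed=seed
                )
                recs = generate_trio_cohort(spec)
                try:
                    res = trios.robust_association(recs, trios.TrioTestConfig())
                except errors.TestNotApplicableError:
                    continue
                hits += res["p_t"] < 0.05
            power[delta] = hits / 12
        assert power[0] <= 0.35
        assert power[15] >= power[5] >= power[0]
        assert power[15] >= 0.8


class TestBattery:
    def _cell(self, n, n_car, seed, delta=0):
        rng = np.random.default_rng(seed)
        copies = np.array([0] * (n - n_car) + [1] * n_car)
        counts = rng.poisson(45 + delta * copies)
        return _records(copies, counts)

    def test_na_bookkeeping_and_bonferroni(self):
        cfg = trios.TrioTestConfig(n_perm=50, seed=0)
        cells = {
            ("chr1", "cohortA", "paternal"): self._cell(40, 10, 1),
            ("chr1", "cohortA", "maternal"): self._cell(40, 3, 2),  # NA
            ("chr2", "cohortB", "paternal"): self._cell(40, 8, 3),
        }
        df = trios.run_trio_battery(cells, cfg)
        assert len(df) == 3
        assert df["performed"].sum() == 2
        assert df.attrs["bonferroni_factor"] == 2
        na = df[~df["performed"]]
        assert na["p_perm"].isna().all()
        ok = df[df["performed"]]
        assert np.allclose(
            ok["p_perm_bonferroni"], np.minimum(ok["p_perm"] * 2, 1.0)
        )

    def test_single_test_factor_one(self):
        cfg = trios.TrioTestConfig(n_perm=50, seed=0)
        cells = {
            ("chr1", "c", "paternal"): self._cell(50, 12, 4, delta=25),
            ("chr2", "c", "paternal"): self._cell(40, 2, 5),  # NA
        }
        df = trios.run_trio_battery(cells, cfg)
        assert df.attrs["bonferroni_factor"] == 1
        performed = df[df["performed"]].iloc[0]
        assert performed["p_perm_bonferroni"] == performed["p_perm"]
        assert bool(performed["significant"])

    def test_empty_cells(self):
        df = trios.run_trio_battery({}, trios.TrioTestConfig(n_perm=10))
        assert len(df) == 0
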