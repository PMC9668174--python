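"""Fold statistics, z-score combination, overlaps, validation regression."""

import numpy as np
import pytest
from scipy import stats

from ritss import (
    Cohort,
    FoldResult,
    ScenarioConfig,
    SplitConfig,
    combine_folds,
    fold_statistic,
    overlap_sets,
    run_ritss,
    simulate_null,
    validation_test,
)


class TestFoldStatistic:
    @pytest.mark.parametrize(
        "u, r, expected_T, expected_s2",
        [
            ([1.0, -1.0], [1.0, 1.0], 0.0, 2.0),
            ([2.0], [3.0], 6.0, 36.0),
        ],
    )
    def test_hand_values(self, u, r, expected_T, expected_s2):
        T, s2 = fold_statistic(np.array(u), np.array(r))
        assert T == pytest.approx(expected_T)
        assert s2 == pytest.approx(expected_s2)

    def test_matches_bruteforce_accumulation(self):
        rng = np.random.default_rng(0)
        u, r = rng.standard_normal(100), rng.standard_normal(100)
        T, s2 = fold_statistic(u, r)
        T_ref = sum(float(u[i]) * float(r[i]) for i in range(100))
        s2_ref = sum((float(u[i]) * float(r[i])) ** 2 for i in range(100))
        assert T == pytest.approx(T_ref, rel=1e-12)
        assert s2 == pytest.approx(s2_ref, rel=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            fold_statistic(np.ones(3), np.ones(4))


class TestCombineFolds:
    def _folds(self, Ts, s2s):
        return [
            FoldResult(k=i, T_k=T, sigma2_k=s2, variant_set=[], n_k=10)
            for i, (T, s2) in enumerate(zip(Ts, s2s))
        ]

    def test_zero_statistic_gives_p_one(self):
        res = combine_folds(self._folds([0.0, 0.0], [1.0, 1.0]))
        assert res.z == 0.0 and res.p_value == pytest.approx(1.0)

    def test_standard_normal_tail_oracle(self):
        # T=(3,1), s2=(4,12) -> z = 4/4 = 1, p = 2*(1 - Phi(1))
        res = combine_folds(self._folds([3.0, 1.0], [4.0, 12.0]))
        assert res.z == pytest.approx(1.0)
        assert res.p_value == pytest.approx(2 * stats.norm.sf(1.0), rel=1e-6)
        assert res.p_value == pytest.approx(0.3173, abs=2e-4)

    def test_all_degenerate_folds_flagged(self):
        res = combine_folds(self._folds([0.0, 0.0], [0.0, 0.0]))
        assert res.degenerate and res.p_value == 1.0 and res.z == 0.0

    def test_z_invariant_under_positive_rescaling(self):
        rng = np.random.default_rng(1)
        u, r = rng.standard_normal(50), rng.standard_normal(50)
        folds = []
        folds_scaled = []
        for k, scale in enumerate([1.0, 1.0]):
            T, s2 = fold_statistic(u, r)
            Ts, s2s = fold_statistic(7.3 * u, r)
            folds.append(FoldResult(k=k, T_k=T, sigma2_k=s2, variant_set=[], n_k=50))
            folds_scaled.append(
                FoldResult(k=k, T_k=Ts, sigma2_k=s2s, variant_set=[], n_k=50)
            )
        assert combine_folds(folds).z == pytest.approx(
            combine_folds(folds_scaled).z, rel=1e-12
        )


class TestOverlapSets:
    @pytest.mark.parametrize(
        "sets, m4, m3",
        [
            ([{"a", "b"}, {"a"}, {"a", "c"}, {"a"}], ["a"], []),
            ([{"a", "b"}, {"a", "b"}, {"a", "b"}, {"a"}], ["a"], ["b"]),
            ([{"x", "y"}] * 4, ["x", "y"], []),
        ],
    )
    def test_counting(self, sets, m4, m3):
        got4, got3 = overlap_sets(sets)
        assert got4 == m4 and got3 == m3

    def test_disjoint_m4_m3(self):
        m4, m3 = overlap_sets([{1, 2}, {1, 3}, {1, 2}, {1, 2}])
        assert set(m4) & set(m3) == set()


class TestValidationTest:
    def _planted(self, n, delta, seed):
        rng = np.random.default_rng(seed)
        X = rng.binomial(2, 0.3, size=(n, 5)).astype(float)
        E = rng.standard_normal((n, 2))
        Z = rng.standard_normal((n, 1))
        w = np.array([0.4, -0.3, 0.2])
        G = X[:, :3] @ w
        Y = 0.3 * E[:, 0] + X @ rng.normal(0, 0.2, 5) + delta * G * E[:, 0]
        Y = Y + rng.standard_normal(n)
        cohort = Cohort(
            sample_ids=[str(i) for i in range(n)], Y=Y, X=X, E=E, Z=Z,
            variant_ids=[f"rs{j}" for j in range(5)],
            env_names=["E1", "E2"], covar_names=["Z1"],
        )
        return cohort, w

    def test_recovers_planted_interaction_effect(self):
        cohort, w = self._planted(n=8000, delta=0.3, seed=0)
        beta, p_model, p_sandwich = validation_test(cohort, [0, 1, 2], w, t=0)
        assert beta == pytest.approx(0.3, abs=0.1)
        assert p_model < 1e-6

    def test_sandwich_matches_model_se_under_homoscedasticity(self):
        cohort, w = self._planted(n=8000, delta=0.2, seed=1)
        beta, p_model, p_sandwich = validation_test(cohort, [0, 1, 2], w, t=0)
        z_m = stats.norm.isf(p_model / 2)
        z_s = stats.norm.isf(p_sandwich / 2)
        assert z_m == pytest.approx(z_s, rel=0.05)

    def test_null_calibration_over_replicates(self):
        rejections = 0
        n_reps = 200
        for seed in range(n_reps):
            cohort, w = self._planted(n=400, delta=0.0, seed=seed)
            _, p_model, _ = validation_test(cohort, [0, 1, 2], w, t=0)
            rejections += p_model < 0.05
        rate = rejections / n_reps
        lo, hi = stats.binom.interval(0.95, n_reps, 0.05)
        assert lo / n_reps <= rate <= hi / n_reps

    def test_empty_variant_set_errors(self, sim_cohort):
        with pytest.raises(ValueError):
            validation_test(sim_cohort, [], np.zeros(sim_cohort.m), t=0)


class TestRunRitss:
    def test_fixed_seed_reproducible(self):
        cohort = simulate_null(ScenarioConfig(n=1500, m=12, d=3, p=2, seed=21))
        cfg = SplitConfig(K=3, seed=5)
        r1 = run_ritss(cohort, 0, strategy=1, split_config=cfg)
        r2 = run_ritss(cohort, 0, strategy=1, split_config=cfg)
        assert r1.z == r2.z and r1.p_value == r2.p_value
        assert [f.variant_set for f in r1.fold_results] == [
            f.variant_set for f in r2.fold_results
        ]

    def test_each_sample_contributes_once(self):
        cohort = simulate_null(ScenarioConfig(n=1500, m=12, d=3, p=2, seed=22))
        res = run_ritss(cohort, 0, strategy=2, split_config=SplitConfig(K=3, seed=2))
        assert sum(f.n_k for f in res.fold_results) == cohort.n

    def test_result_serialization(self, tmp_path):
        cohort = simulate_null(ScenarioConfig(n=1500, m=12, d=3, p=2, seed=23))
        res = run_ritss(cohort, 0, strategy=2, split_config=SplitConfig(K=3, seed=3))
        res.write_json(tmp_path / "res.json", cohort.variant_ids)
        import json

        obj = json.loads((tmp_path / "res.json").read_text())
        assert {"z", "p_value", "folds", "m4", "m3"} <= obj.keys()
        table = res.membership_table(cohort.variant_ids)
        if len(table):
            assert "n_folds" in table.columns
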