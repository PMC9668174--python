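"""Screening strategies and score combination."""

import numpy as np
import pytest

from ritss import (
    Cohort,
    ScenarioConfig,
    combine_scores,
    screen_strategy1,
    screen_strategy2,
    simulate_null,
)
from ritss.screening import _grid_sizes


def _planted_cohort(n=4000, m=30, n_signal=2, effect=0.6, seed=0, dense=False):
    """Cohort with genuine variant-by-E1 interactions at known variants."""
    rng = np.random.default_rng(seed)
    maf = rng.uniform(0.2, 0.5, size=m)
    X = rng.binomial(2, maf, size=(n, m)).astype(float)
    E = rng.standard_normal((n, 2))
    Z = rng.standard_normal((n, 1))
    pi0 = rng.normal(0, 0.3, size=m)
    if dense:
        signal = np.argsort(-np.abs(pi0))[:n_signal]
        delta = effect * pi0[signal]
    else:
        signal = np.arange(n_signal)
        delta = np.full(n_signal, effect)
    Y = 0.5 * E[:, 0] + X @ pi0 + (X[:, signal] @ delta) * E[:, 0]
    Y = Y + rng.standard_normal(n)
    cohort = Cohort(
        sample_ids=[str(i) for i in range(n)],
        Y=Y, X=X, E=E, Z=Z,
        variant_ids=[f"rs{j}" for j in range(m)],
        env_names=["E1", "E2"], covar_names=["Z1"],
    )
    return cohort, set(int(j) for j in signal)


def test_grid_rule_appends_terminal_size():
    assert _grid_sizes(10, 5, 23) == [10, 15, 20, 23]
    assert _grid_sizes(10, 5, 10) == [10]
    assert _grid_sizes(10, 5, 7) == [7]


class TestStrategy1:
    def test_weights_are_linear_fit_pi0(self, sim_cohort):
        rows = np.arange(sim_cohort.n)
        out = screen_strategy1(sim_cohort, rows, t=0, seed=1)
        D = np.hstack(
            [np.ones((sim_cohort.n, 1)), sim_cohort.E, sim_cohort.Z, sim_cohort.X]
        )
        pi0, *_ = np.linalg.lstsq(D, sim_cohort.Y, rcond=None)
        pi0 = pi0[1 + sim_cohort.d + sim_cohort.p:]
        for spec in out.candidate_scores:
            for j, l, w in spec.terms:
                assert l == 0
                assert w == pytest.approx(pi0[j], abs=1e-8)

    def test_recovers_dense_risk_score_subcomponent(self):
        """Strong subcomponent signal: J1 must capture most planted variants."""
        hits, total = 0, 0
        for seed in range(3):
            cohort, signal = _planted_cohort(
                n=6000, m=25, n_signal=10, effect=0.5, seed=seed, dense=True
            )
            out = screen_strategy1(cohort, np.arange(cohort.n), t=0, seed=seed)
            j1 = {j for j, _, _ in out.candidate_scores[0].terms}
            hits += len(j1 & signal)
            total += len(signal)
        assert hits / total >= 0.8

    def test_depends_only_on_given_rows(self, sim_cohort):
        rows = np.arange(0, 600)
        out1 = screen_strategy1(sim_cohort, rows, t=0, seed=3)
        mutated = Cohort(
            sample_ids=sim_cohort.sample_ids,
            Y=np.where(np.arange(sim_cohort.n) >= 600, 0.0, sim_cohort.Y),
            X=sim_cohort.X, E=sim_cohort.E, Z=sim_cohort.Z,
            variant_ids=sim_cohort.variant_ids,
            env_names=sim_cohort.env_names, covar_names=sim_cohort.covar_names,
        )
        out2 = screen_strategy1(mutated, rows, t=0, seed=3)
        assert [s.terms for s in out1.candidate_scores] == [
            s.terms for s in out2.candidate_scores
        ]


class TestStrategy2:
    def test_recovers_planted_strong_pair(self):
        recovered = 0
        n_reps = 10
        for seed in range(n_reps):
            cohort, signal = _planted_cohort(
                n=3000, m=20, n_signal=2, effect=0.6, seed=100 + seed
            )
            out = screen_strategy2(cohort, np.arange(cohort.n), t=0)
            j1 = {j for j, _, _ in out.candidate_scores[0].terms}
            recovered += signal <= j1
        assert recovered >= int(0.95 * n_reps)

    def test_all_unit_pvalues_give_empty_scores(self, tiny_cohort, monkeypatch):
        # constant phenotype: every per-variant scan is a null fit with p = 1
        cohort = tiny_cohort
        cohort.Y = np.zeros(cohort.n)
        out = screen_strategy2(cohort, np.arange(cohort.n), t=0)
        assert out.candidate_scores[0].terms == []
        assert out.candidate_scores[1].terms == []

    def test_weights_match_per_variant_interaction_fit(self, sim_cohort):
        """Scan weights equal statsmodels per-variant interaction estimates."""
        import statsmodels.api as sm

        rows = np.arange(sim_cohort.n)
        out = screen_strategy2(sim_cohort, rows, t=0, q2=1.1)  # include everything
        weights = {j: w for j, _, w in out.candidate_scores[0].terms}
        weights.update({j: w for j, _, w in out.candidate_scores[1].terms})
        for j in (0, 7, 14):
            D = np.column_stack(
                [
                    np.ones(sim_cohort.n),
                    sim_cohort.E,
                    sim_cohort.Z,
                    sim_cohort.X[:, j],
                    sim_cohort.X[:, j] * sim_cohort.E[:, 0],
                ]
            )
            ref = sm.OLS(sim_cohort.Y, D).fit().params[-1]
            assert weights[j] == pytest.approx(ref, rel=1e-8)


class TestCombineScores:
    def test_gate_keeps_only_significant_second_score(self):
        cohort, _ = _planted_cohort(n=3000, m=20, n_signal=2, effect=0.8, seed=7)
        rows = np.arange(cohort.n)
        out = screen_strategy2(cohort, rows, t=0)
        combined = combine_scores(cohort, rows, out)
        u1_vars = {j for j, _, _ in out.candidate_scores[0].terms}
        u2_vars = {j for j, _, _ in out.candidate_scores[1].terms}
        if combined.gate_c2:
            assert combined.gate_p_value < 0.05
            assert set(combined.variant_set) == u1_vars | u2_vars
        else:
            assert combined.gate_p_value is None or combined.gate_p_value >= 0.05
            assert set(combined.variant_set) == u1_vars

    def test_combined_weights_copied_not_refit(self, sim_cohort):
        rows_screen = np.arange(0, 600)
        rows_combine = np.arange(600, 1200)
        out = screen_strategy1(sim_cohort, rows_screen, t=0, seed=5)
        combined = combine_scores(sim_cohort, rows_combine, out)
        screen_weights = {
            (j, l): w
            for spec in out.candidate_scores
            for j, l, w in spec.terms
        }
        for j, l, w in combined.spec.terms:
            assert w == screen_weights[(j, l)]

    def test_both_empty_gives_degenerate_combined(self, sim_cohort):
        from ritss import InteractionScoreSpec
        from ritss.screening import ScreenOutput

        out = ScreenOutput(
            candidate_scores=[
                InteractionScoreSpec(label="U1"),
                InteractionScoreSpec(label="U2"),
            ],
            env_index=0,
        )
        combined = combine_scores(sim_cohort, np.arange(sim_cohort.n), out)
        assert combined.spec.terms == [] and combined.variant_set == []
        assert combined.gate_c2 == 0
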