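"""Generator correctness: beta solving, allocation, cell probabilities,
trial invariants and marginal moments."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import expit, logit

import steppedwedge as sw
from steppedwedge.datagen import DegenerateScenarioError


class TestSolveBetaParams:
    @pytest.mark.parametrize(
        "mu,icc,a,b",
        [(0.1, 0.01, 9.9, 89.1), (0.2, 0.1, 1.8, 7.2)],
    )
    def test_known_solutions(self, mu, icc, a, b):
        params = sw.solve_beta_params(mu, icc)
        assert params.a == pytest.approx(a, abs=1e-12)
        assert params.b == pytest.approx(b, abs=1e-12)
        # substitution oracle: the moment equations hold
        assert params.a / (params.a + params.b) == pytest.approx(mu, abs=1e-12)
        assert 1 / (params.a + params.b + 1) == pytest.approx(icc, abs=1e-12)

    def test_numerical_integration_of_density_recovers_moments(self):
        params = sw.solve_beta_params(0.1, 0.01)
        dist = stats.beta(params.a, params.b)
        mean, var = dist.stats(moments="mv")
        assert mean == pytest.approx(0.1, abs=1e-10)
        # var(p) = mu(1-mu) rho for the beta-induced ICC
        assert var / (0.1 * 0.9) == pytest.approx(0.01, abs=1e-10)

    def test_symmetric_mean_gives_equal_shapes(self):
        for icc in (0.01, 0.3, 0.9):
            params = sw.solve_beta_params(0.5, icc)
            assert params.a == pytest.approx(params.b, rel=1e-12)

    @given(mu=st.floats(0.01, 0.99), icc=st.floats(0.001, 0.99))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_round_trip_property(self, mu, icc):
        params = sw.solve_beta_params(mu, icc)
        assert params.a > 0 and params.b > 0
        assert params.mean == pytest.approx(mu, rel=1e-9)
        assert params.icc == pytest.approx(icc, rel=1e-9)

    @pytest.mark.parametrize("mu,icc", [(0.0, 0.1), (1.0, 0.1), (0.5, 0.0),
                                        (0.5, 1.0), (-0.1, 0.5)])
    def test_domain_errors(self, mu, icc):
        with pytest.raises(ValueError):
            sw.solve_beta_params(mu, icc)


class TestAllocateSteps:
    def test_equal_groups_and_full_coverage(self):
        rng = np.random.default_rng(0)
        alloc = sw.allocate_steps(3, 3, rng)
        assert sorted(alloc.values()) == [1, 2, 3]
        alloc = sw.allocate_steps(6, 3, rng)
        counts = np.bincount(list(alloc.values()))[1:]
        assert list(counts) == [2, 2, 2]

    def test_indivisible_raises(self):
        with pytest.raises(ValueError):
            sw.allocate_steps(7, 3, np.random.default_rng(0))

    def test_allocation_uniform_over_clusters(self):
        # chi-square goodness of fit: each cluster should land in each step
        # group with probability 1/steps
        rng = np.random.default_rng(12345)
        m, steps, draws = 6, 3, 6000
        counts = np.zeros((m, steps))
        for _ in range(draws):
            alloc = sw.allocate_steps(m, steps, rng)
            for k, g in alloc.items():
                counts[k - 1, g - 1] += 1
        expected = draws / steps
        chi2 = ((counts - expected) ** 2 / expected).sum()
        # df = m*(steps-1); keep alpha small so the seeded test is stable
        assert chi2 < stats.chi2(m * (steps - 1)).ppf(0.999)


class TestCellProbability:
    def test_intervention_doubles_point_one_to_point_two(self):
        p = sw.cell_probability(logit(0.1), 1, 0, np.log(2.25), 0.0)
        assert p == pytest.approx(0.2, abs=1e-12)

    def test_baseline_cell_recovers_p0(self):
        for b1, b2 in [(0.7, 0.3), (-2.0, 5.0)]:
            assert sw.cell_probability(logit(0.1), 0, 0, b1, b2) == pytest.approx(
                0.1, abs=1e-12)

    def test_two_periods_of_time_trend(self):
        # independent odds arithmetic: 0.1 -> odds 1/9, times 1.227^2
        odds = (0.1 / 0.9) * 1.227**2
        expected = odds / (1 + odds)
        p = sw.cell_probability(logit(0.1), 0, 2, 0.0, np.log(1.227))
        assert p == pytest.approx(expected, abs=1e-12)
        assert p == pytest.approx(0.1433, abs=5e-4)

    @given(beta1_lo=st.floats(-2, 2), delta=st.floats(0, 3),
           p0=st.floats(0.05, 0.95), j=st.integers(0, 6))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_monotone_in_intervention_effect(self, beta1_lo, delta, p0, j):
        lo = sw.cell_probability(logit(p0), 1, j, beta1_lo, 0.1)
        hi = sw.cell_probability(logit(p0), 1, j, beta1_lo + delta, 0.1)
        assert hi >= lo
        assert 0.0 < lo < 1.0 and 0.0 < hi < 1.0


class TestGenerateTrial:
    def test_dataset_invariants(self, small_trial):
        cells = small_trial.cells
        for _, grp in cells.groupby("cluster"):
            x = grp.sort_values("period")["treatment"].to_numpy()
            assert np.all(np.diff(x) >= 0), "treatment must be absorbing"
        assert (cells.loc[cells["period"] == 0, "treatment"] == 0).all()
        last = cells["period"].max()
        assert (cells.loc[cells["period"] == last, "treatment"] == 1).all()
        assert ((cells["events"] >= 0) & (cells["events"] <= cells["n"])).all()
        assert cells.loc[cells["treatment"] == 0, "events"].sum() >= 1
        assert cells.loc[cells["treatment"] == 1, "events"].sum() >= 1

    def test_treatment_matrix_is_stepped_wedge_pattern(self, small_trial):
        mat = small_trial.treatment_matrix()
        m, t = mat.shape
        per_step = m // (t - 1)
        expected = np.zeros_like(mat)
        for row in range(m):
            expected[row, 1 + row // per_step:] = 1
        assert np.array_equal(mat, expected)

    def test_discard_rule_always_leaves_events_in_both_arms(self):
        # tiny cells and rare events make all-zero arms likely before the
        # discard rule; afterwards both arms must always contain an event
        cfg = sw.ScenarioConfig(steps=3, n_clusters=3, cell_size=2,
                                baseline_mean=0.05, icc=0.05,
                                or_intervention=1.0, replicates=1, seed=0)
        discards = 0
        for s in range(200):
            trial = sw.generate_trial(cfg, np.random.SeedSequence(s))
            cells = trial.cells
            assert cells.loc[cells["treatment"] == 0, "events"].sum() >= 1
            assert cells.loc[cells["treatment"] == 1, "events"].sum() >= 1
            discards += trial.n_discarded
        assert discards > 0, "test should exercise the discard path"

    def test_degenerate_scenario_raises(self):
        cfg = sw.ScenarioConfig(steps=3, n_clusters=3, cell_size=1,
                                baseline_mean=1e-4, icc=0.01,
                                or_intervention=1.0, replicates=1, seed=0)
        with pytest.raises(DegenerateScenarioError):
            sw.generate_trial(cfg, np.random.SeedSequence(0))

    def test_null_grand_event_rate_matches_baseline_mean(self):
        # law of total expectation: with beta1 = beta2 = 0 every cell has
        # expectation mu
        mu = 0.1
        cfg = sw.ScenarioConfig(steps=3, n_clusters=6, cell_size=10,
                                baseline_mean=mu, icc=0.05,
                                or_intervention=1.0, or_time=1.0,
                                replicates=1, seed=0)
        streams = np.random.SeedSequence(77).spawn(2000)
        events = n = 0
        for s in streams:
            trial = sw.generate_trial(cfg, s)
            events += trial.cells["events"].sum()
            n += trial.total_n
        se = np.sqrt(mu * (1 - mu) / n)
        # the discard rule slightly inflates the rate in tiny trials; use
        # 4 MC SEs of headroom
        assert abs(events / n - mu) < 4 * se

    def test_baseline_draws_match_target_mean_and_icc(self):
        # moment oracle on the drawn p_0k: mean mu, var mu(1-mu)rho
        mu, rho = 0.2, 0.1
        cfg = sw.ScenarioConfig(steps=3, n_clusters=9, cell_size=10,
                                baseline_mean=mu, icc=rho,
                                or_intervention=1.0, replicates=1, seed=0)
        p0 = []
        for s in np.random.SeedSequence(123).spawn(1500):
            trial = sw.generate_trial(cfg, s)
            p0.extend(trial.cells.loc[trial.cells["period"] == 0, "p0"])
        p0 = np.asarray(p0)
        var_target = mu * (1 - mu) * rho
        assert p0.mean() == pytest.approx(mu, abs=3 * p0.std() / np.sqrt(len(p0)))
        icc_hat = p0.var(ddof=1) / (p0.mean() * (1 - p0.mean()))
        assert icc_hat == pytest.approx(rho, abs=0.01)
        assert p0.var(ddof=1) == pytest.approx(var_target, rel=0.12)

    def test_large_cells_concentrate_on_drawn_p0(self):
        # with beta1 = beta2 = 0 and huge cells, observed proportions
        # converge to the drawn cluster proportions
        cfg = sw.ScenarioConfig(steps=3, n_clusters=3, cell_size=10_000,
                                baseline_mean=0.1, icc=0.05,
                                or_intervention=1.0, or_time=1.0,
                                replicates=1, seed=0)
        trial = sw.generate_trial(cfg, np.random.SeedSequence(21))
        cells = trial.cells
        phat = cells["events"] / cells["n"]
        tol = 3 * np.sqrt(cells["p0"] * (1 - cells["p0"]) / cells["n"])
        assert (np.abs(phat - cells["p0"]) < tol).all()

    def test_common_random_numbers_monotone_in_effect(self):
        cfg = sw.ScenarioConfig(steps=3, n_clusters=6, cell_size=10,
                                baseline_mean=0.1, icc=0.05,
                                or_intervention=1.5, or_time=1.227,
                                replicates=1, seed=0)
        lo = sw.generate_trial(cfg, np.random.SeedSequence(9))
        hi = sw.generate_trial(cfg.with_(or_intervention=3.0),
                               np.random.SeedSequence(9))
        assert np.allclose(lo.cells["p0"], hi.cells["p0"]), "CRN broken"
        treated = lo.cells["treatment"] == 1
        assert (hi.cells.loc[treated, "p_true"].to_numpy()
                >= lo.cells.loc[treated, "p_true"].to_numpy()).all()

    def test_reproducible_given_seed(self):
        cfg = sw.ScenarioConfig(replicates=1, seed=0)
        a = sw.generate_trial(cfg, np.random.SeedSequence(4))
        b = sw.generate_trial(cfg, np.random.SeedSequence(4))
        assert a.cells.equals(b.cells)
        assert a.step_allocation == b.step_allocation

    def test_csv_export_round_trip(self, small_trial, tmp_path):
        path = tmp_path / "cells.csv"
        small_trial.to_csv(path)
        import pandas as pd
        back = pd.read_csv(path)
        assert list(back.columns) == ["cluster", "period", "treatment", "n",
                                      "events", "p_true"]
        assert len(back) == len(small_trial.cells)
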