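"""Bootstrap, triad-reassignment permutation test, per-bat statistics and
rank models, checked against exhaustive and brute-force oracles on toy
designs."""

import dataclasses
import math
from itertools import permutations, product

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bondperm import (
    DegenerateStatisticError,
    SimConfig,
    bootstrap_mean_ci,
    dyad_changes,
    generate_colony,
    group_change_summary,
    phase_correlations,
    proportion_unfamiliar_shift,
    rank_lm_change,
    rank_lm_post,
    tradeoff_correlation,
    triad_assignment_space,
    triad_permutation_test,
)
from bondperm.inference import TriadAssignmentSpace, _test_dyad_table

from conftest import TOY_PHASES, TOY_SESSIONS, build_colony


def toy_three_site_colony(seed=101, delta=0.8):
    """3 sites x 2 bats: the smallest design with 3-dyad cages (4 assignments)."""
    return generate_colony(
        SimConfig(
            n_sites=3, bats_per_site=2, phase_lengths_days=(30, 7, 30),
            treatment_effect_delta=delta, seed=seed,
        )
    )


class TestBootstrap:
    def test_constant_vector_degenerate_ci(self):
        res = bootstrap_mean_ci([2.5] * 8, n_boot=200, seed=0)
        assert (res.estimate, res.ci_low, res.ci_high) == (2.5, 2.5, 2.5)

    def test_seed_reproducibility(self):
        values = np.arange(10.0)
        a = bootstrap_mean_ci(values, n_boot=500, seed=7)
        b = bootstrap_mean_ci(values, n_boot=500, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert np.array_equal(a.null_distribution, b.null_distribution)
        c = bootstrap_mean_ci(values, n_boot=500, seed=8)
        assert not np.array_equal(a.null_distribution, c.null_distribution)

    def test_ci_ordered_and_brackets_bulk(self):
        rng = np.random.default_rng(3)
        res = bootstrap_mean_ci(rng.normal(5, 2, 80), n_boot=2000, seed=1)
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_mean_ci([])


class TestGroupSummary:
    def test_all_zero_changes(self):
        changes = pd.DataFrame(
            {"dyad_class": ["TEST", "TEST", "CONTROL", "FAMILIAR"], "delta_log": [0.0] * 4}
        )
        out = group_change_summary(changes, n_boot=100, seed=0)
        assert out["test_mean_change"].estimate == 0.0
        assert out["test_minus_control"].estimate == 0.0

    def test_difference_of_known_means(self):
        changes = pd.DataFrame(
            {"dyad_class": ["TEST", "TEST", "CONTROL", "CONTROL"], "delta_log": [1.0, 1.0, 0.0, 0.0]}
        )
        out = group_change_summary(changes, n_boot=100, seed=0)
        assert out["test_minus_control"].estimate == 1.0

    def test_missing_class_warns_and_skips(self):
        changes = pd.DataFrame({"dyad_class": ["TEST", "TEST"], "delta_log": [0.5, 0.7]})
        with pytest.warns(UserWarning, match="CONTROL"):
            out = group_change_summary(changes, n_boot=100, seed=0)
        assert "control_mean_change" not in out
        assert "test_minus_control" not in out


class TestAssignmentSpace:
    @pytest.mark.parametrize(
        "n_sites, per_site, expected",
        [(3, 2, 4), (2, 2, 2), (2, 3, 6), (3, 3, 36)],
    )
    def test_count_matches_brute_force(self, n_sites, per_site, expected):
        bats_by_site = [[f"s{i}b{j}" for j in range(per_site)] for i in range(n_sites)]
        space = TriadAssignmentSpace(bats_by_site)
        assert space.count == expected
        assignments = space.all()
        assert len(assignments) == expected
        # distinct as unlabeled partitions
        as_partitions = {frozenset(frozenset(t) for t in a) for a in assignments}
        assert len(as_partitions) == expected
        # brute force: enumerate all ways to partition into site-complete groups
        brute = set()
        for perms in product(*(permutations(s) for s in bats_by_site)):
            brute.add(frozenset(frozenset(col[k] for col in perms) for k in range(per_site)))
        assert as_partitions == brute

    def test_paper_design_count_only(self):
        space = TriadAssignmentSpace([[f"s{i}b{j}" for j in range(7)] for i in range(3)])
        assert space.count == math.factorial(7) ** 2 == 25_401_600
        with pytest.raises(ValueError, match="max_count"):
            space.all(max_count=1000)

    def test_unequal_sites_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            TriadAssignmentSpace([["a", "b"], ["c"]])

    def test_sampler_covers_space(self):
        space = TriadAssignmentSpace([["a0", "a1"], ["b0", "b1"], ["c0", "c1"]])
        rng = np.random.default_rng(0)
        seen = {space.sample(rng) for _ in range(200)}
        assert len(seen) == 4


class TestTriadPermutationTest:
    def test_identity_statistic_in_null(self, small_colony):
        res = triad_permutation_test(small_colony, n_perm=50, seed=0, exhaustive_cap=0)
        # observed assignment drawn by the sampler reproduces the estimate
        space = triad_assignment_space(small_colony)
        site_of = small_colony.site_of()
        observed = tuple(
            tuple(sorted(grp["bat_id"], key=lambda b: site_of[b]))
            for _, grp in small_colony.triads.groupby("triad_id")
        )
        from bondperm.inference import _assignment_stats, _delta_matrix

        mat, index = _delta_matrix(small_colony, dyad_changes(small_colony))
        idx = np.array([[[index[b] for b in tri] for tri in observed]])
        upper = mat[np.triu_indices(mat.shape[0], k=1)]
        s = float(np.nansum(upper))
        c = int(np.isfinite(upper).sum())
        assert _assignment_stats(mat, idx, s, c)[0] == pytest.approx(res.estimate, abs=1e-12)

    def test_all_equal_deltas_give_p_one(self):
        colony = toy_three_site_colony(delta=0.0)
        changes = dyad_changes(colony)
        changes = changes.assign(delta_log=0.3)  # perfectly exchangeable
        res = triad_permutation_test(colony, n_perm=200, seed=1, changes=changes)
        assert res.estimate == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_exhaustive_used_on_toy_design(self):
        colony = toy_three_site_colony()
        res = triad_permutation_test(colony, n_perm=10, seed=0)
        assert res.n_resamples == 4  # (2!)^2 assignments enumerated
        assert res.p_value >= 0.25

    def test_monte_carlo_converges_to_exhaustive(self):
        colony = toy_three_site_colony(seed=5)
        exact = triad_permutation_test(colony, n_perm=10, seed=0)  # exhaustive (4 states)
        mc = triad_permutation_test(colony, n_perm=4000, seed=1, exhaustive_cap=0)
        se = math.sqrt(exact.p_value * (1 - exact.p_value) / 4000)
        assert abs(mc.p_value - exact.p_value) <= 3 * se + 1 / 4001

    def test_p_value_bounds(self, small_colony):
        res = triad_permutation_test(small_colony, n_perm=99, seed=3, exhaustive_cap=0)
        assert 1 / 100 <= res.p_value <= 1.0

    def test_invariant_to_bat_renaming(self, small_colony):
        renamed = {b: f"z_{b}" for b in small_colony.bat_ids}  # order-preserving
        colony2 = small_colony.replace(
            bats=small_colony.bats.assign(bat_id=small_colony.bats["bat_id"].map(renamed)),
            triads=small_colony.triads.assign(bat_id=small_colony.triads["bat_id"].map(renamed)),
            bouts=small_colony.bouts.assign(
                actor=small_colony.bouts["actor"].map(renamed),
                receiver=small_colony.bouts["receiver"].map(renamed),
            ),
        )
        r1 = triad_permutation_test(small_colony, n_perm=300, seed=9, exhaustive_cap=0)
        r2 = triad_permutation_test(colony2, n_perm=300, seed=9, exhaustive_cap=0)
        assert r1.estimate == pytest.approx(r2.estimate, abs=1e-12)
        assert r1.p_value == r2.p_value

    def test_detects_large_injected_effect(self, default_colony):
        res = triad_permutation_test(default_colony, n_perm=500, seed=2)
        assert res.p_value < 0.05


class TestProportionShift:
    def test_identical_phases_give_zero(self):
        colony = build_colony(
            bats=[("a1", "X"), ("a2", "X"), ("b1", "Y"), ("b2", "Y")],
            triads=[("t1", "a1"), ("t1", "b1"), ("t2", "a2"), ("t2", "b2")],
            sessions=[("2020-01-01", "PRE", 4.0), ("2020-01-02", "FORCED", 4.0),
                      ("2020-01-03", "POST", 4.0)],
            bouts=[
                ("2020-01-01", "a1", "b1", 40.0), ("2020-01-03", "a1", "b1", 40.0),
                ("2020-01-01", "a1", "a2", 20.0), ("2020-01-03", "a1", "a2", 20.0),
            ],
            phases=[("PRE", "2020-01-01", "2020-01-01"), ("FORCED", "2020-01-02", "2020-01-02"),
                    ("POST", "2020-01-03", "2020-01-03")],
        )
        res = proportion_unfamiliar_shift(colony, n_boot=100, seed=0)
        assert res.estimate == pytest.approx(0.0, abs=1e-12)
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_post_boost_shifts_proportion_up(self, default_colony):
        res = proportion_unfamiliar_shift(default_colony, n_boot=500, seed=1)
        assert res.estimate > 0.0

    def test_bat_without_grooming_dropped_with_warning(self, toy_colony):
        with pytest.warns(UserWarning, match="dropped"):
            proportion_unfamiliar_shift(toy_colony, n_boot=50, seed=0)


class TestTradeoffCorrelation:
    def test_perfectly_coupled_changes_give_r_one(self):
        """With delta = g(site_a) + g(site_b), each bat's familiar mean change
        is 2*g(s) and its unfamiliar mean is g(s)/2 + const: the per-actor
        changes to the two partner types are a perfect linear (increasing)
        function of each other, so r = 1 exactly."""
        colony = toy_three_site_colony(seed=3)
        changes = dyad_changes(colony)
        site_of = colony.site_of()
        g = {site: float(i) for i, site in enumerate(colony.sites)}
        coupled = changes.assign(
            delta_log=[g[site_of[a]] + g[site_of[b]] for a, b in zip(changes["bat_a"], changes["bat_b"])]
        )
        res = tradeoff_correlation(colony, n_boot=100, seed=0, changes=coupled)
        assert res.estimate == pytest.approx(1.0, abs=1e-9)

    def test_constant_vector_degenerate(self):
        colony = toy_three_site_colony(seed=4)
        changes = dyad_changes(colony)
        flat = changes.assign(
            delta_log=np.where(changes["dyad_class"] == "FAMILIAR", 0.5, changes["delta_log"])
        )
        with pytest.raises(DegenerateStatisticError):
            tradeoff_correlation(colony, n_boot=50, seed=0, changes=flat)

    def test_default_colony_estimate_matches_scipy(self, default_colony):
        changes = dyad_changes(default_colony)
        fam, unfam = [], []
        for bat in default_colony.bat_ids:
            sub = changes[(changes["bat_a"] == bat) | (changes["bat_b"] == bat)]
            fam.append(sub.loc[sub["dyad_class"] == "FAMILIAR", "delta_log"].mean())
            unfam.append(sub.loc[sub["dyad_class"] != "FAMILIAR", "delta_log"].mean())
        r, p = stats.pearsonr(fam, unfam)
        res = tradeoff_correlation(default_colony, n_boot=200, seed=0)
        assert res.estimate == pytest.approx(r, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)


class TestRankModels:
    def test_matches_linregress_on_single_predictor(self):
        colony = toy_three_site_colony(seed=6)
        wide = _test_dyad_table(colony)
        res = rank_lm_change(colony, n_perm=100, seed=0)
        manual = stats.linregress(
            stats.rankdata(wide["FORCED"]), stats.rankdata(wide["delta_log"])
        )
        assert res.estimate == pytest.approx(manual.slope, abs=1e-10)
        assert res.parametric_p == pytest.approx(manual.pvalue, abs=1e-10)

    def test_identically_ordered_response_gives_beta_one(self):
        """Predictor and response in the same order with no ties: rank slope 1."""
        from bondperm.inference import _rank_lm

        forced = np.array([0.3, 1.1, 0.7, 2.0, 1.6, 0.1])
        y = 10.0 * forced + 2.0  # same ordering, different scale
        groups = [np.array([0, 1, 2]), np.array([3, 4, 5])]
        res = _rank_lm(y, forced, groups, None, 100, 0, 1000, "beta")
        assert res.estimate == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_constant_predictor_rejected(self):
        colony = generate_colony(
            SimConfig(n_sites=3, bats_per_site=2, phase_lengths_days=(5, 3, 5),
                      base_rate_lambda=0.0, seed=1)
        )
        with pytest.raises(DegenerateStatisticError):
            rank_lm_change(colony, n_perm=10, seed=0)

    def test_exhaustive_within_cage_null_on_two_cage_toy(self):
        colony = toy_three_site_colony(seed=12)
        res = rank_lm_change(colony, n_perm=10, seed=0)  # (3!)^2 = 36 <= cap
        assert res.n_resamples == 36
        assert res.p_value >= 1 / 36

    def test_mc_matches_exhaustive_within_three_se(self):
        colony = toy_three_site_colony(seed=13)
        exact = rank_lm_change(colony, n_perm=10, seed=0)
        mc = rank_lm_change(colony, n_perm=3000, seed=5, exhaustive_cap=0)
        se = math.sqrt(exact.p_value * (1 - exact.p_value) / 3000)
        assert abs(mc.p_value - exact.p_value) <= 3 * se + 1 / 3001

    def test_permutation_p_uniform_under_independence(self):
        """Forced-phase ranks carry no signal about the change under the null
        generator; one-sided permutation p should look uniform."""
        ps = []
        for i in range(60):
            colony = generate_colony(
                SimConfig(
                    seed=500 + i, phase_lengths_days=(10, 7, 10), treatment_effect_delta=0.0
                )
            )
            ps.append(rank_lm_change(colony, n_perm=200, seed=i).p_value)
        d, p = stats.kstest(ps, "uniform")
        assert p > 0.001

    def test_same_seed_identical_permutation_p(self, small_colony):
        a = rank_lm_post(small_colony, n_perm=300, seed=4)
        b = rank_lm_post(small_colony, n_perm=300, seed=4)
        assert a.p_value == b.p_value and a.estimate == b.estimate

    def test_post_tracks_forced_when_coupled(self):
        """Inflating the treated-phase rates couples POST to FORCED; the
        forced coefficient should come out clearly positive."""
        colony = generate_colony(
            SimConfig(seed=77, treatment_effect_delta=1.5, dyad_sd=1.2, phase_lengths_days=(21, 7, 21))
        )
        res = rank_lm_post(colony, n_perm=300, seed=0)
        assert res.estimate > 0.2


class TestPhaseCorrelations:
    def test_matches_direct_spearman_on_test_dyads(self):
        colony = toy_three_site_colony(seed=21)
        out = phase_correlations(colony)
        wide = _test_dyad_table(colony)
        for other, key in (("POST", "spearman_forced_post"), ("PRE", "spearman_forced_pre")):
            rho, p = stats.spearmanr(wide["FORCED"], wide[other])
            assert out[key].estimate == pytest.approx(rho, abs=1e-12)
            assert out[key].p_value == pytest.approx(p, abs=1e-12)

    def test_constant_rates_degenerate(self):
        colony = generate_colony(
            SimConfig(n_sites=3, bats_per_site=2, phase_lengths_days=(5, 3, 5),
                      base_rate_lambda=0.0, seed=2)
        )
        with pytest.raises(DegenerateStatisticError):
            phase_correlations(colony)
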