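"""Local-community dynamics: geometry, survival, recruitment, annual cycle."""

import math

import numpy as np
import pytest
from scipy import stats

from neutralforest.local_dynamics import (
    Arena,
    CommunityState,
    Params,
    SimConfig,
    annual_step,
    circle_overlap_area,
    competition_index,
    competition_loads,
    immigration_rate,
    lognormal_kernel_params,
    run_simulation,
    sample_recruit_location,
    survival_probability,
)
from neutralforest.metacommunity import build_metacommunity


def _random_state(n, arena, rng, n_species=5):
    return CommunityState(
        x=rng.uniform(0, arena.width, n),
        y=rng.uniform(0, arena.height, n),
        species=rng.integers(0, n_species, n),
        ids=np.arange(n),
        arena=arena,
        next_id=n,
    )


class TestImmigrationRate:
    def test_default_arena_geometry(self):
        arena = Arena()
        assert arena.perimeter == 3000.0
        assert arena.area == 5e5

    def test_zero_distance(self):
        assert immigration_rate(0.0, Arena()) == 0.0

    def test_formula_value(self):
        # P*d_m/(pi*A) = 3000*30/(pi*5e5)
        assert immigration_rate(30.0, Arena()) == pytest.approx(0.057296, abs=1e-6)

    def test_clamped_to_one(self):
        assert immigration_rate(1e6, Arena()) == 1.0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            immigration_rate(-1.0, Arena())


class TestLognormalKernel:
    def test_equal_mean_sd_gives_log2_variance(self):
        mu, sigma = lognormal_kernel_params(30.0, 30.0)
        assert sigma**2 == pytest.approx(math.log(2))
        assert mu == pytest.approx(math.log(30) - math.log(2) / 2)

    def test_degenerate_limit(self):
        mu, sigma = lognormal_kernel_params(30.0, 1e-9)
        assert sigma == pytest.approx(0.0, abs=1e-6)
        assert mu == pytest.approx(math.log(30.0), abs=1e-6)

    def test_sampled_moments(self, rng):
        d_m, d_sd, n = 30.0, 45.0, 10**6
        mu, sigma = lognormal_kernel_params(d_m, d_sd)
        x = rng.lognormal(mu, sigma, n)
        assert abs(x.mean() - d_m) < 3 * x.std(ddof=1) / np.sqrt(n)
        # s.e. of the sample s.d. via the fourth moment
        m4 = np.mean((x - x.mean()) ** 4)
        se_sd = np.sqrt((m4 - x.var() ** 2) / n) / (2 * x.std())
        assert abs(x.std(ddof=1) - d_sd) < 3 * se_sd

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            lognormal_kernel_params(0.0, 1.0)
        with pytest.raises(ValueError):
            lognormal_kernel_params(1.0, -1.0)


class TestCircleOverlap:
    def test_coincident(self):
        assert circle_overlap_area(0.0, 2.0) == pytest.approx(math.pi * 4.0)

    def test_disjoint(self):
        assert circle_overlap_area(4.0, 2.0) == 0.0
        assert circle_overlap_area(5.0, 2.0) == 0.0

    def test_monte_carlo_lens_area(self):
        """Unit-disc pair at distance 1: hit-or-miss integration oracle."""
        r = np.random.default_rng(123)
        n = 10**6
        pts = r.uniform([-1, -1], [2, 1], size=(n, 2))
        inside = (np.hypot(pts[:, 0], pts[:, 1]) < 1) & (
            np.hypot(pts[:, 0] - 1.0, pts[:, 1]) < 1
        )
        mc_area = inside.mean() * 6.0  # bounding box area
        exact = circle_overlap_area(1.0, 1.0)
        assert exact == pytest.approx(2 * math.acos(0.5) - 0.5 * math.sqrt(3))
        assert abs(mc_area - exact) / exact < 0.01


class TestSurvival:
    def test_no_competition_gives_baseline(self):
        assert survival_probability(0.0, 0.98, 1.0) == 0.98

    def test_halving_load(self):
        for b_s in (0.5, 0.98, 1.0):
            assert survival_probability(7.3, b_s, 7.3) == pytest.approx(b_s / 2)

    def test_asymptote_and_monotonicity(self):
        c = np.linspace(0, 1e6, 101)
        s = survival_probability(c, 0.99, 2.0)
        assert np.all(np.diff(s) < 0)
        assert s[-1] < 1e-4


class TestCompetition:
    def test_isolated_tree(self, rng):
        state = _random_state(1, Arena(100, 100), rng)
        assert competition_index(state, 0, 5.0) == 0.0

    def test_coincident_neighbour_counts_one(self):
        state = CommunityState(
            x=np.array([10.0, 10.0]),
            y=np.array([20.0, 20.0]),
            species=np.array([0, 1]),
            ids=np.arange(2),
            arena=Arena(100, 100),
        )
        assert competition_index(state, 0, 3.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_spatial_index_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        arena = Arena(60, 40)
        state = _random_state(200, arena, rng)
        for r_t in (2.0, 5.0):
            fast = competition_loads(state.x, state.y, r_t)
            brute = np.array(
                [competition_index(state, i, r_t) for i in range(state.size)]
            )
            np.testing.assert_allclose(fast, brute, atol=1e-9)

    def test_mean_load_increases_with_radius(self, rng):
        state = _random_state(500, Arena(100, 100), rng)
        means = [competition_loads(state.x, state.y, r).mean() for r in (2.0, 5.0, 10.0)]
        assert means[0] < means[1] < means[2]


class TestRecruitLocation:
    def test_always_inside_arena(self, rng):
        arena = Arena(50, 30)
        kernel = lognormal_kernel_params(20.0, 30.0)
        xs = np.empty(10**4)
        ys = np.empty(10**4)
        for i in range(10**4):
            xs[i], ys[i] = sample_recruit_location((1.0, 1.0), kernel, arena, rng)
        assert np.all((xs >= 0) & (xs < 50) & (ys >= 0) & (ys < 30))

    def test_mean_distance_in_large_arena(self, rng):
        arena = Arena(10_000, 10_000)
        kernel = lognormal_kernel_params(30.0, 20.0)
        n = 20_000
        d = np.empty(n)
        for i in range(n):
            x, y = sample_recruit_location((5000.0, 5000.0), kernel, arena, rng)
            d[i] = math.hypot(x - 5000.0, y - 5000.0)
        assert abs(d.mean() - 30.0) < 3 * d.std(ddof=1) / np.sqrt(n)

    def test_degenerate_kernel_places_on_circle(self, rng):
        arena = Arena(1000, 1000)
        for _ in range(100):
            x, y = sample_recruit_location((500.0, 500.0), (math.log(10.0), 0.0), arena, rng)
            assert math.hypot(x - 500, y - 500) == pytest.approx(10.0, abs=1e-9)


class TestAnnualStep:
    def _setup(self, j=500, seed=0, theta=20.0):
        rng = np.random.default_rng(seed)
        arena = Arena(120, 100)
        meta = build_metacommunity(theta, 10_000, rng)
        params = Params(r_t=3.0, b_s=0.98, a_s=5.0, d_m=20.0, d_sd=30.0, theta=theta)
        state = _random_state(j, arena, rng, n_species=meta.n_species)
        return state, params, meta, rng

    def test_zero_sum_conservation(self):
        state, params, meta, rng = self._setup()
        for _ in range(20):
            _, deaths = annual_step(state, params, meta, rng)
            assert state.size == 500
        assert state.year == 20
        assert state.cumulative_deaths >= 0

    def test_no_mortality_limit(self):
        state, params, meta, rng = self._setup()
        calm = Params(r_t=3.0, b_s=1.0, a_s=1e9, d_m=20.0, d_sd=30.0, theta=20.0)
        x0, y0 = state.x.copy(), state.y.copy()
        _, deaths = annual_step(state, calm, meta, rng)
        assert deaths == 0
        assert np.array_equal(state.x, x0) and np.array_equal(state.y, y0)
        assert state.year == 1

    def test_mean_deaths_matches_bernoulli_sum(self):
        """Replicated single steps from a frozen state: E[deaths] = sum(1 - s_j)."""
        state, params, meta, _ = self._setup(j=400, seed=3)
        c = competition_loads(state.x, state.y, params.r_t)
        p_death = 1.0 - survival_probability(c, params.b_s, params.a_s)
        expected = p_death.sum()
        var = np.sum(p_death * (1 - p_death))
        reps = 500
        rng = np.random.default_rng(77)
        deaths = np.empty(reps)
        for k in range(reps):
            frozen = CommunityState(
                x=state.x.copy(), y=state.y.copy(), species=state.species.copy(),
                ids=state.ids.copy(), arena=state.arena, next_id=state.next_id,
            )
            _, deaths[k] = annual_step(frozen, params, meta, rng)
        se = np.sqrt(var / reps)
        assert abs(deaths.mean() - expected) < 3 * se

    def test_per_capita_neutrality_across_species(self):
        """With identical parameters for all, deaths are independent of species.

        Chi-square over species of aggregated death counts from replicated
        single steps against the competition-derived expectation.
        """
        state, params, meta, _ = self._setup(j=600, seed=9, theta=5.0)
        c = competition_loads(state.x, state.y, params.r_t)
        p_death = 1.0 - survival_probability(c, params.b_s, params.a_s)
        reps = 200
        rng = np.random.default_rng(31)
        n_sp = int(state.species.max()) + 1
        observed = np.zeros(n_sp)
        for _ in range(reps):
            frozen = CommunityState(
                x=state.x.copy(), y=state.y.copy(), species=state.species.copy(),
                ids=state.ids.copy(), arena=state.arena, next_id=state.next_id,
            )
            survivors_before = frozen.ids.copy()
            annual_step(frozen, params, meta, rng)
            died = ~np.isin(survivors_before, frozen.ids)
            observed += np.bincount(state.species[died], minlength=n_sp)
        expected = reps * np.array(
            [p_death[state.species == s].sum() for s in range(n_sp)]
        )
        keep = expected >= 5
        chi2, p = stats.chisquare(observed[keep], expected[keep] * observed[keep].sum() / expected[keep].sum())
        assert p > 0.01


class TestRunSimulation:
    def test_determinism_and_bounds(self):
        params = Params(r_t=2.0, b_s=0.97, a_s=5.0, d_m=15.0, d_sd=20.0, theta=30.0)
        cfg = SimConfig(j=300, arena=Arena(100, 80), burn_in_generations=3, meta_j_m=10_000)
        a = run_simulation(params, cfg, seed=5)
        b = run_simulation(params, cfg, seed=5)
        assert a.final_state.size == 300
        assert np.array_equal(a.final_state.x, b.final_state.x)
        assert np.array_equal(a.final_state.species, b.final_state.species)
        assert 1 <= len(np.unique(a.final_state.species)) <= 300
        assert a.generations_elapsed >= 3.0
        assert a.annual_death_counts.sum() == a.final_state.cumulative_deaths

    def test_richness_increases_with_theta(self):
        cfg = SimConfig(j=400, arena=Arena(120, 90), burn_in_generations=5, meta_j_m=20_000)
        rich = {}
        for theta in (5.0, 100.0):
            params = Params(r_t=2.0, b_s=0.97, a_s=5.0, d_m=15.0, d_sd=20.0, theta=theta)
            r = [
                len(np.unique(run_simulation(params, cfg, seed=s).final_state.species))
                for s in range(10)
            ]
            rich[theta] = np.mean(r)
        assert rich[5.0] < rich[100.0]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(j=0)
        with pytest.raises(ValueError):
            SimConfig(burn_in_generations=0)
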