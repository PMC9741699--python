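import numpy as np
import pytest

from metadiss import free_energy as FE
from metadiss.errors import (
    InsufficientReplicatesError,
    InvalidParameterError,
    UndefinedCorrelationError,
)
from metadiss.plumed_io import CVSeries, HillsRecord
from metadiss.synthetic import (
    KB,
    LangevinParams,
    PotentialSpec,
    simulate_langevin_metadynamics,
)

BETA = 1.0 / (KB * 300.0)


def single_hill(center=1.0, sigma=0.05, height=0.1, t=1.0):
    return HillsRecord(
        times=np.array([t]),
        centers=np.array([center]),
        sigmas=np.array([sigma]),
        heights=np.array([height]),
    )


class TestBiasPotential:
    def test_peak_value(self):
        v = FE.bias_potential(single_hill(), np.array([1.0]))
        assert v[0] == pytest.approx(0.1)

    def test_one_sigma_point(self):
        v = FE.bias_potential(single_hill(), np.array([1.05]))
        assert v[0] == pytest.approx(0.1 * np.exp(-0.5), rel=1e-9)

    def test_until_time_before_first_event(self):
        grid = np.linspace(0, 2, 50)
        v = FE.bias_potential(single_hill(t=10.0), grid, until_time=5.0)
        assert np.all(v == 0.0)

    def test_empty_grid_rejected(self):
        with pytest.raises(InvalidParameterError):
            FE.bias_potential(single_hill(), np.array([]))


class TestFesFromBias:
    def test_zero_hills_flat(self):
        hills = HillsRecord(np.array([]), np.array([]), np.array([]), np.array([]))
        prof = FE.fes_from_bias(hills, np.linspace(0, 1, 20))
        assert np.all(prof.F == 0.0)

    def test_single_hill_inverted_and_shifted(self):
        grid = np.linspace(0.0, 2.0, 201)
        prof = FE.fes_from_bias(single_hill(), grid)
        assert prof.F.min() == 0.0
        assert prof.F[np.argmin(np.abs(grid - 1.0))] == pytest.approx(0.0)
        assert prof.F.max() == pytest.approx(0.1, abs=1e-6)


class TestCOfT:
    def test_zero_bias_gives_zero(self):
        hills = single_hill(height=0.0)
        ctx = FE.compute_c_of_t(hills, np.linspace(0, 2, 100))
        np.testing.assert_allclose(ctx.c_of_t, 0.0, atol=1e-12)

    def test_uniform_bias_gives_shift(self):
        # a very wide Gaussian is spatially uniform over a narrow grid
        hills = single_hill(center=0.5, sigma=1e4, height=0.7)
        ctx = FE.compute_c_of_t(hills, np.linspace(0.4, 0.6, 50))
        assert ctx.c_of_t[0] == pytest.approx(0.7, rel=1e-6)

    def test_narrow_hill_matches_quadrature(self):
        grid = np.linspace(0.0, 10.0, 20001)
        hills = single_hill(center=5.0, sigma=0.05, height=0.5)
        ctx = FE.compute_c_of_t(hills, grid)
        v = FE.bias_potential(hills, grid)
        quad = np.log(np.trapezoid(np.exp(BETA * v), grid) / 10.0) / BETA
        assert ctx.c_of_t[0] == pytest.approx(quad, rel=1e-3)
        # and the closed-form small-bias approximation is close
        approx = np.log(1 + 0.5 * 0.05 * np.sqrt(2 * np.pi) * BETA / 10.0) / BETA
        assert ctx.c_of_t[0] == pytest.approx(approx, rel=0.1)


class TestReweightedHistogram:
    def test_zero_bias_equals_plain_histogram(self):
        rng = np.random.default_rng(0)
        cv = CVSeries(times=np.arange(5000.0), values=rng.normal(0, 0.5, 5000))
        hills = HillsRecord(np.array([]), np.array([]), np.array([]), np.array([]))
        grid = np.linspace(-2, 2, 101)
        ctx = FE.compute_c_of_t(hills, grid)
        dens = FE.reweighted_histogram(cv, hills, ctx, grid)
        edges = np.empty(len(grid) + 1)
        edges[1:-1] = 0.5 * (grid[:-1] + grid[1:])
        edges[0] = grid[0] - 0.5 * (grid[1] - grid[0])
        edges[-1] = grid[-1] + 0.5 * (grid[-1] - grid[-2])
        plain, _ = np.histogram(cv.values, bins=edges)
        np.testing.assert_allclose(dens, plain / plain.sum(), atol=1e-12)

    def test_density_normalised(self, double_well_run):
        cv, hills = double_well_run
        grid = np.linspace(-1.5, 1.5, 151)
        ctx = FE.compute_c_of_t(hills, grid)
        dens = FE.reweighted_histogram(cv, hills, ctx, grid)
        assert dens.sum() == pytest.approx(1.0, abs=1e-12)

    def test_recovers_boltzmann_density(self, double_well, double_well_run):
        cv, hills = double_well_run
        grid = np.linspace(-1.5, 1.5, 151)
        ctx = FE.compute_c_of_t(hills, grid)
        dens = FE.reweighted_histogram(cv, hills, ctx, grid)
        p_true = np.exp(-BETA * double_well.energy(grid))
        p_true /= p_true.sum()
        assert 0.5 * np.abs(dens - p_true).sum() < 0.1  # total variation


class TestCombineAndDepth:
    def test_identical_densities_fixed_point(self):
        grid = np.linspace(0, 1, 50)
        p = np.exp(-((grid - 0.5) ** 2) / 0.02)
        p /= p.sum()
        single = FE.combine_runs([p], grid=grid)
        multi = FE.combine_runs([p, p, p], run_weights=[1, 5, 2], grid=grid)
        np.testing.assert_allclose(multi.F, single.F, atol=1e-10)

    def test_disjoint_deltas_weight_ratio(self):
        grid = np.linspace(0, 1, 11)
        p1 = np.zeros(11); p1[2] = 1.0
        p2 = np.zeros(11); p2[8] = 1.0
        prof = FE.combine_runs([p1, p2], run_weights=[3.0, 1.0], grid=grid)
        assert prof.F[8] - prof.F[2] == pytest.approx(np.log(3.0) / BETA, rel=1e-9)

    def test_zero_total_weight_rejected(self):
        with pytest.raises(InvalidParameterError):
            FE.combine_runs([np.ones(5) / 5], run_weights=[0.0])

    def test_inversion_round_trip_identity(self):
        rng = np.random.default_rng(1)
        grid = np.linspace(0, 1, 64)
        p = rng.random(64) + 0.01
        p /= p.sum()
        prof = FE.combine_runs([p], grid=grid)
        back = FE.density_from_profile(prof)
        np.testing.assert_allclose(back, p, atol=1e-10)

    def test_energy_offset_invariance(self):
        grid = np.linspace(0, 2, 100)
        f = 5.0 * (grid - 0.5) ** 2
        prof = FE.FreeEnergyProfile(grid=grid, F=f - f.min())
        shifted = FE.FreeEnergyProfile(grid=grid, F=f - f.min() + 7.0)
        d1 = FE.minimum_depth(prof, (0.0, 1.0))
        d2 = FE.minimum_depth(shifted, (0.0, 1.0))
        assert d1 == pytest.approx(d2)

    def test_flat_profile_depth_zero(self):
        grid = np.linspace(0, 1, 30)
        prof = FE.FreeEnergyProfile(grid=grid, F=np.zeros(30))
        assert FE.minimum_depth(prof, (0.0, 0.5)) == 0.0

    def test_tabulated_double_well_depths(self):
        """Wells 10 and 6 kJ/mol below the barrier top."""
        grid = np.linspace(-1.5, 1.5, 601)
        f = (
            -10.0 * np.exp(-((grid + 0.5) ** 2) / (2 * 0.14**2))
            - 6.0 * np.exp(-((grid - 0.5) ** 2) / (2 * 0.14**2))
        )
        prof = FE.FreeEnergyProfile(grid=grid, F=f - f.min())
        assert FE.minimum_depth(prof, (-1.0, 0.0)) == pytest.approx(10.0, abs=0.01)
        assert FE.minimum_depth(prof, (0.0, 1.0)) == pytest.approx(6.0, abs=0.01)

    def test_bound_region_outside_grid_rejected(self):
        prof = FE.FreeEnergyProfile(grid=np.linspace(0, 1, 10), F=np.zeros(10))
        with pytest.raises(InvalidParameterError):
            FE.minimum_depth(prof, (5.0, 6.0))


class TestLooDepth:
    def _runs(self, n=3, seed=0, n_steps=300_000):
        pot = PotentialSpec.double_well(
            positions=(-0.5, 0.5), depths=(12.0, 8.0), domain=(-1.5, 1.5)
        )
        return [
            simulate_langevin_metadynamics(
                pot, LangevinParams(n_steps=n_steps, seed=seed + r),
                deposit_stride=1000, save_stride=200,
            )
            for r in range(n)
        ]

    def test_identical_runs_collapse_interval(self):
        cv, hills = self._runs(1)[0]
        est = FE.loo_depth([(cv, hills)] * 4, bound_region=(-1.0, 0.0))
        assert est.loo_min == pytest.approx(est.mean_depth)
        assert est.loo_max == pytest.approx(est.mean_depth)

    def test_interval_orders_and_counts(self):
        runs = self._runs(4, seed=3)
        est = FE.loo_depth(runs, bound_region=(-1.0, 0.0))
        assert est.loo_min <= est.mean_depth <= est.loo_max
        assert est.n_runs == 4
        assert est.mean_depth >= 0

    def test_too_few_runs(self):
        runs = self._runs(2)
        with pytest.raises(InsufficientReplicatesError):
            FE.loo_depth(runs, bound_region=(-1.0, 0.0))

    def test_combining_runs_beats_median_single(self, double_well):
        """More metadynamics data gives a better profile (L2 on the grid)."""
        pot = PotentialSpec.double_well(
            positions=(-0.5, 0.5), depths=(12.0, 8.0), domain=(-1.5, 1.5)
        )
        runs = [
            simulate_langevin_metadynamics(
                pot,
                LangevinParams(n_steps=1_000_000, seed=11 + r),
                deposit_stride=500,
                save_stride=200,
            )
            for r in range(6)
        ]
        grid = FE.default_grid([c for c, _ in runs], [h for _, h in runs])
        truth = double_well.energy(grid)
        truth -= truth.min()

        def l2(profile):
            sel = np.isfinite(profile.F) & (np.abs(grid) < 1.2)
            return np.sqrt(((profile.F[sel] - truth[sel]) ** 2).mean())

        dens = [
            FE.density_from_profile(FE.fes_from_bias(h, grid, time_average_fraction=0.3))
            for _, h in runs
        ]
        combined = l2(FE.combine_runs(dens, grid=grid))
        singles = sorted(l2(FE.combine_runs([d], grid=grid)) for d in dens)
        median_single = singles[len(singles) // 2]
        assert combined < median_single


class TestCorrelateDepthTm:
    def test_exact_linear_relation(self):
        depths = [2.0, 4.0, 6.0, 8.0]
        tm = [60.0, 65.0, 70.0, 75.0]
        corr = FE.correlate_depth_tm(depths, tm)
        assert corr.pearson == pytest.approx(1.0)
        assert corr.spearman == pytest.approx(1.0)

    def test_tmless_system_excluded_and_reported(self):
        depths = [2.0, 4.0, 6.0, 8.0]
        tm = [60.0, None, 70.0, 75.0]
        corr = FE.correlate_depth_tm(depths, tm)
        assert corr.excluded == [1]
        assert corr.n_used == 3

    def test_degenerate_depths_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            FE.correlate_depth_tm([1.0, 1.0, 1.0], [60.0, 65.0, 70.0])

    def test_too_few_tm_systems(self):
        with pytest.raises(InsufficientReplicatesError):
            FE.correlate_depth_tm([1.0, 2.0, 3.0], [60.0, None, None])
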