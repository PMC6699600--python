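import numpy as np
import pytest

from porescope.centerline import Profile, uniform_grid
from porescope.constants import KB_KJ_PER_MOL_K
from porescope.fixtures import FixtureSpec, make_pore, place_waters
from porescope.solvent import (
    KdeConfig,
    amise_bandwidth,
    analyze_solvent,
    detect_dewetted,
    free_energy,
    kde_1d,
    number_density,
)

KT = KB_KJ_PER_MOL_K * 298.15  # ~2.479 kJ/mol


def flat_profile(lo, hi, spacing, value, quantity):
    s = uniform_grid(lo, hi, spacing)
    return Profile(s=s, values=np.full(len(s), float(value)), quantity=quantity)


class TestKde:
    def test_single_sample_peak(self):
        h = 0.1
        p = kde_1d(np.array([0.0]), KdeConfig(bandwidth=h, grid_spacing=0.01, s_range=(-1, 1)))
        peak = p.values[np.argmin(np.abs(p.s))]
        assert peak == pytest.approx(1.0 / (h * np.sqrt(2 * np.pi)), rel=1e-9)

    def test_identical_samples_equal_single_sample(self):
        cfg = KdeConfig(bandwidth=0.1, grid_spacing=0.01, s_range=(-1, 1))
        one = kde_1d(np.array([0.0]), cfg)
        many = kde_1d(np.zeros(50), cfg)
        np.testing.assert_allclose(one.values, many.values, rtol=1e-12)

    def test_normalization(self):
        rng = np.random.default_rng(1)
        samples = rng.normal(0.0, 0.5, 5000)
        h = 0.14
        lo, hi = samples.min() - 8 * h, samples.max() + 8 * h
        p = kde_1d(samples, KdeConfig(bandwidth=h, grid_spacing=h / 20, s_range=(lo, hi)))
        assert np.trapezoid(p.values, p.s) == pytest.approx(1.0, abs=1e-6)

    def test_default_bandwidth_beats_extremes_on_bimodal_mixture(self):
        rng = np.random.default_rng(2)
        n = 2000
        sd = 0.5
        samples = np.where(rng.random(n) < 0.5, rng.normal(-1.2, sd, n), rng.normal(1.2, sd, n))
        grid = uniform_grid(-4.0, 4.0, 0.01)
        true = 0.5 * (np.exp(-((grid + 1.2) ** 2) / (2 * sd**2))
                      + np.exp(-((grid - 1.2) ** 2) / (2 * sd**2)))
        true /= sd * np.sqrt(2 * np.pi)

        def l2(h):
            p = kde_1d(samples, KdeConfig(bandwidth=h), grid=grid)
            return np.sqrt(np.trapezoid((p.values - true) ** 2, grid))

        assert l2(0.14) < l2(0.01)
        assert l2(0.14) < l2(2.0)

    def test_empty_samples_raise(self):
        with pytest.raises(ValueError, match="at least one"):
            kde_1d(np.array([]), KdeConfig())


class TestAmiseBandwidth:
    def test_normal_reference_rule(self):
        rng = np.random.default_rng(3)
        samples = rng.normal(0, 1, 50_000)
        expected = 1.06 * np.std(samples) * len(samples) ** (-0.2)
        assert amise_bandwidth(samples) == pytest.approx(expected, rel=0.01)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        samples = rng.normal(0, 1, 1000)
        assert amise_bandwidth(2 * samples) == pytest.approx(2 * amise_bandwidth(samples), rel=1e-12)

    def test_sample_size_rate(self):
        rng = np.random.default_rng(5)
        samples = rng.normal(0, 1, 2000)
        quadrupled = np.tile(samples, 4)
        ratio = amise_bandwidth(quadrupled) / amise_bandwidth(samples)
        assert ratio == pytest.approx(4 ** (-0.2), rel=0.01)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            amise_bandwidth(np.ones(10))


class TestNumberDensity:
    def test_uniform_limit(self):
        length, radius, n = 4.0, 0.4, 1000
        p = flat_profile(0, length, 0.1, 1.0 / length, "density")
        r = flat_profile(0, length, 0.1, radius, "radius")
        nd = number_density(p, n, r)
        np.testing.assert_allclose(nd.values, n / (np.pi * radius**2 * length))

    def test_doubling_radius_quarters_density(self):
        p = flat_profile(0, 1, 0.1, 1.0, "density")
        r1 = flat_profile(0, 1, 0.1, 0.2, "radius")
        r2 = flat_profile(0, 1, 0.1, 0.4, "radius")
        np.testing.assert_allclose(number_density(p, 10, r1).values,
                                   4 * number_density(p, 10, r2).values)

    def test_nonpositive_radius_raises(self):
        p = flat_profile(0, 1, 0.1, 1.0, "density")
        r = flat_profile(0, 1, 0.1, 0.0, "radius")
        with pytest.raises(ValueError, match="positive"):
            number_density(p, 10, r)

    def test_grid_mismatch_raises(self):
        p = flat_profile(0, 1, 0.1, 1.0, "density")
        r = flat_profile(0, 2, 0.1, 0.3, "radius")
        with pytest.raises(ValueError, match="grids"):
            number_density(p, 10, r)

    def test_fixture_filled_at_prescribed_density(self):
        frame, oracle = make_pore(FixtureSpec())
        target = 10_000.0  # nm^-3, scaled up so counting error is small
        s_lo, s_hi = -2.2, 2.2
        s_dense = np.linspace(s_lo, s_hi, 2000)
        volume = np.trapezoid(np.pi * np.asarray(oracle.radius(s_dense)) ** 2, s_dense)
        n = int(round(target * volume))
        wet = place_waters(frame, oracle, None, n, seed=9, s_range=(s_lo, s_hi))
        from porescope.centerline import fit_centerline, radius_function
        from porescope.pathway import find_pathway
        trace = find_pathway(frame)
        spline = fit_centerline(trace)
        radius = radius_function(spline, trace)
        sol = analyze_solvent(wet, spline, radius)
        lo, hi = oracle.interior_band(margin=0.5)
        mask = (sol.number_density.s >= lo) & (sol.number_density.s <= hi)
        assert sol.number_density.values[mask].mean() == pytest.approx(target, rel=0.03)
        np.testing.assert_allclose(sol.number_density.values[mask], target, rtol=0.10)


class TestFreeEnergy:
    def test_uniform_density_gives_zero(self):
        p = flat_profile(0, 4, 0.1, 0.25, "density")
        r = flat_profile(0, 4, 0.1, 0.3, "radius")
        g = free_energy(p, r, KdeConfig(), n_waters=1000)
        np.testing.assert_allclose(g.values, 0.0, atol=1e-9)

    def test_e_fold_ratio_gives_kt_barrier(self):
        s = uniform_grid(0, 4, 0.1)
        values = np.full(len(s), 0.3)
        interior = (s > 1.5) & (s < 2.5)
        values[interior] = 0.3 * np.exp(-1.0)
        p = Profile(s=s, values=values, quantity="density")
        r = flat_profile(0, 4, 0.1, 0.3, "radius")
        g = free_energy(p, r, KdeConfig(), bulk_band=[(0.0, 1.0), (3.0, 4.0)], n_waters=10_000)
        assert g.values[interior].max() == pytest.approx(KT, rel=1e-6)

    def test_bulk_mean_is_zero(self):
        rng = np.random.default_rng(8)
        s = uniform_grid(0, 4, 0.1)
        p = Profile(s=s, values=0.2 + 0.05 * rng.random(len(s)), quantity="density")
        r = flat_profile(0, 4, 0.1, 0.3, "radius")
        band = [(0.0, 0.4), (3.6, 4.0)]
        g = free_energy(p, r, KdeConfig(), bulk_band=band, n_waters=1000)
        mask = ((s >= 0) & (s <= 0.4)) | ((s >= 3.6) & (s <= 4.0))
        assert abs(g.values[mask].mean()) < 1e-9

    def test_dehydrated_points_flagged_not_infinite(self):
        s = uniform_grid(0, 4, 0.1)
        values = np.full(len(s), 0.3)
        values[18:22] = 0.0
        p = Profile(s=s, values=values, quantity="density")
        r = flat_profile(0, 4, 0.1, 0.3, "radius")
        g = free_energy(p, r, KdeConfig(), n_waters=100)
        assert g.flags[18:22].all()
        assert not g.flags[:10].any()
        assert np.all(np.isfinite(g.values))

    def test_fully_dehydrated_bulk_raises(self):
        p = flat_profile(0, 4, 0.1, 0.0, "density")
        r = flat_profile(0, 4, 0.1, 0.3, "radius")
        with pytest.raises(ValueError, match="bulk"):
            free_energy(p, r, KdeConfig(), n_waters=100)


class TestDetectDewetted:
    def test_uniform_profile_no_intervals(self):
        n = flat_profile(0, 4, 0.1, 33.0, "number_density")
        assert detect_dewetted(n, 0.2, 0.5) == []

    def test_single_dry_run_detected(self):
        s = uniform_grid(0, 4, 0.1)
        values = np.full(len(s), 33.0)
        dry = (s >= 1.4) & (s <= 2.6)
        values[dry] = 0.0
        n = Profile(s=s, values=values, quantity="number_density")
        intervals = detect_dewetted(n, 0.2, 0.5, bulk_band=[(0, 1), (3, 4)])
        assert len(intervals) == 1
        lo, hi = intervals[0]
        assert hi - lo == pytest.approx(1.2, abs=0.1 + 1e-9)

    def test_short_runs_filtered(self):
        s = uniform_grid(0, 4, 0.1)
        values = np.full(len(s), 33.0)
        values[5:8] = 0.0
        values[30:33] = 0.0
        n = Profile(s=s, values=values, quantity="number_density")
        assert detect_dewetted(n, 0.2, 0.5, bulk_band=[(1.0, 2.5)]) == []


@pytest.fixture(scope="module")
def hourglass_waters_s(hourglass, hourglass_analysis):
    frame, oracle = hourglass

    def barrier(s):
        return 6.0 * np.exp(-(s**2) / (2 * 0.3**2))

    wet = place_waters(frame, oracle, barrier, 20_000, seed=12)
    from porescope.solvent import water_arc_positions
    return water_arc_positions(wet, hourglass_analysis["spline"])


class TestRecoveryAndSensitivity:
    def test_bandwidth_sensitivity_monotone(self, hourglass_waters_s, hourglass_analysis):
        # small h -> noisy, deep dry waist minimum; large h -> washed-out
        # profiles; assessed inside the pore, away from the mouth regions
        radius = hourglass_analysis["radius"]
        interior = np.abs(radius.s) <= 1.0
        n_waters = len(hourglass_waters_s)
        min_density, max_barrier = [], []
        bulk = [(-2.0, -1.5), (1.5, 2.0)]  # watered, away from waist and grid edges
        for h in [0.05, 0.1, 0.2, 0.5, 1.0]:
            cfg = KdeConfig(bandwidth=h)
            p = kde_1d(hourglass_waters_s, cfg, grid=radius.s)
            nd = number_density(p, n_waters, radius)
            g = free_energy(p, radius, cfg, bulk_band=bulk, n_waters=n_waters)
            min_density.append(nd.values[interior].min())
            # dehydrated points carry their lower-bound value
            max_barrier.append(g.values[interior].max())
        assert all(np.diff(min_density) >= -1e-9)
        # small-h estimates are noisy; allow a small stochastic slack
        assert all(np.diff(max_barrier) <= 0.1)

    def test_barrier_recovery(self, cylinder, cylinder_analysis):
        frame, oracle = cylinder

        def barrier(s):
            return 5.0 * np.exp(-(s**2) / (2 * 0.5**2))

        wet = place_waters(frame, oracle, barrier, 40_000, seed=21)
        sol = analyze_solvent(wet, cylinder_analysis["spline"], cylinder_analysis["radius"],
                              bulk_band=[(-2.4, -1.8), (1.8, 2.4)])
        central = np.abs(sol.free_energy.s) < 1.0
        assert sol.free_energy.values[central].max() == pytest.approx(5.0, abs=0.6)

    def test_no_waters_returns_none(self, cylinder, cylinder_analysis):
        frame, _ = cylinder
        assert analyze_solvent(frame, cylinder_analysis["spline"], cylinder_analysis["radius"]) is None


class TestKdeConfig:
    def test_bad_bandwidth_string(self):
        with pytest.raises(ValueError):
            KdeConfig(bandwidth="auto")

    def test_amise_mode_resolves(self):
        cfg = KdeConfig(bandwidth="amise")
        rng = np.random.default_rng(0)
        assert cfg.resolve_bandwidth(rng.normal(size=100)) > 0

    def test_negative_temperature(self):
        with pytest.raises(ValueError):
            KdeConfig(temperature=-1.0)
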