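"""Fixed-lambda decomposition and free-half-life validation fits."""

import numpy as np
import pytest

from cherenkov_xsec.decay import (
    exposure_integrated_basis,
    fit_fixed_lambda,
    fit_free_halflife,
    resolve_component_profiles,
)
from cherenkov_xsec.nuclides import DecayComponent, default_components, get_component
from cherenkov_xsec.preprocess import DepthProfileSeries

FRAME_TIMES = np.arange(120.0, 3600.0, 5.0)
EXPOSURE = 5.0


def make_series(amplitudes, variance=1.0, mask=None, components=None):
    """Noise-free series whose light curves are exact basis combinations."""
    comps = components or default_components()
    x = exposure_integrated_basis(comps, FRAME_TIMES, EXPOSURE)
    amplitudes = np.atleast_2d(np.asarray(amplitudes, dtype=float))
    intensity = amplitudes @ x.T
    n_depth = amplitudes.shape[0]
    return DepthProfileSeries(
        depth_grid=(np.arange(n_depth) + 0.5) * 0.0133,
        frame_times=FRAME_TIMES,
        exposure=EXPOSURE,
        intensity=intensity,
        variance=np.full_like(intensity, variance),
        mask=np.zeros(n_depth, bool) if mask is None else np.asarray(mask, bool),
    )


class TestFixedLambda:
    def test_exact_recovery_of_known_mixture(self):
        """100/50/20 mixture of the three bases comes back to machine precision."""
        series = make_series([[100.0, 50.0, 20.0]])
        fit = fit_fixed_lambda(series, default_components())
        assert np.allclose(fit.amplitudes[0], [100.0, 50.0, 20.0], rtol=1e-10)

    def test_pure_single_component(self):
        series = make_series([[0.0, 75.0, 0.0]])
        fit = fit_fixed_lambda(series, default_components())
        assert fit.amplitudes[0, 1] == pytest.approx(75.0, rel=1e-10)
        assert abs(fit.amplitudes[0, 0]) < 1e-8
        assert abs(fit.amplitudes[0, 2]) < 1e-8

    def test_matches_explicit_normal_equations(self):
        """Solution equals the brute-force (X^T W X)^-1 X^T W y solve."""
        rng = np.random.default_rng(7)
        comps = default_components()
        x = exposure_integrated_basis(comps, FRAME_TIMES, EXPOSURE)
        true_amp = np.array([80.0, 30.0, 10.0])
        y = x @ true_amp + rng.normal(0, 0.5, len(FRAME_TIMES))
        var = rng.uniform(0.5, 2.0, len(FRAME_TIMES))
        series = make_series([true_amp])
        series.intensity[0] = y
        series.variance[0] = var
        fit = fit_fixed_lambda(series, comps, baseline=False)
        w = np.diag(1.0 / var)
        expected = np.linalg.solve(x.T @ w @ x, x.T @ w @ y)
        assert np.allclose(fit.amplitudes[0], expected, rtol=1e-8)
        assert np.allclose(fit.covariances[0], np.linalg.inv(x.T @ w @ x), rtol=1e-8)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(3)
        comps = default_components()
        x = exposure_integrated_basis(comps, FRAME_TIMES, EXPOSURE)
        y = x @ np.array([10.0, 5.0, 2.0]) + rng.normal(0, 1.0, len(FRAME_TIMES))
        series = make_series([[0, 0, 0]])
        series.intensity[0] = y
        fit = fit_fixed_lambda(series, comps, baseline=False)
        resid = y - x @ fit.amplitudes[0]
        assert np.allclose(x.T @ resid, 0.0, atol=1e-6 * np.abs(y).sum())

    def test_identical_decay_constants_rejected(self):
        comps = [get_component("15O"),
                 DecayComponent("15O-twin", 122.2, 1.0, 0.99)]
        series = make_series([[1.0, 1.0]], components=comps)
        with pytest.raises(ValueError, match="15O"):
            fit_fixed_lambda(series, comps)

    def test_too_few_frames_rejected(self):
        series = make_series([[1.0, 1.0, 1.0]])
        with pytest.raises(ValueError, match="frames"):
            fit_fixed_lambda(series, default_components(), window=(120.0, 160.0))

    def test_masked_bins_stay_masked(self):
        series = make_series([[10, 5, 2], [10, 5, 2]], mask=[True, False])
        fit = fit_fixed_lambda(series, default_components())
        assert np.all(np.isnan(fit.amplitudes[0]))
        assert np.all(np.isfinite(fit.amplitudes[1]))
        resolved = resolve_component_profiles(fit)
        assert resolved.mask[0] and not resolved.mask[1]
        assert np.isnan(resolved.profiles["15O"][0])

    def test_nonnegative_option(self):
        rng = np.random.default_rng(11)
        x = exposure_integrated_basis(default_components(), FRAME_TIMES, EXPOSURE)
        y = x @ np.array([0.5, 0.0, 0.1]) + rng.normal(0, 2.0, len(FRAME_TIMES))
        series = make_series([[0, 0, 0]])
        series.intensity[0] = y
        fit = fit_fixed_lambda(series, default_components(), nonnegative=True)
        assert np.all(fit.amplitudes[0] >= 0)

    def test_amplitude_coverage_near_68_percent(self):
        """Over repeated noise draws the 1-sigma interval covers truth at the
        nominal rate (binomial slack at 300 draws)."""
        rng = np.random.default_rng(2024)
        comps = default_components()
        x = exposure_integrated_basis(comps, FRAME_TIMES, EXPOSURE)
        true_amp = np.array([100.0, 40.0, 15.0])
        sigma_noise = 2.0
        cov = np.linalg.inv(x.T @ x / sigma_noise**2)
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            y = x @ true_amp + rng.normal(0, sigma_noise, len(FRAME_TIMES))
            a = np.linalg.solve(x.T @ x, x.T @ y)
            if abs(a[0] - true_amp[0]) <= np.sqrt(cov[0, 0]):
                hits += 1
        assert hits / n_rep == pytest.approx(0.68, abs=0.07)


class TestFreeHalfLife:
    def test_single_exponential_recovers_15o_half_life(self):
        c = get_component("15O")
        series = make_series([[100.0]], components=[c])
        res = fit_free_halflife(FRAME_TIMES, EXPOSURE, series.intensity[0],
                                1, [100.0])
        assert res.success
        assert res.half_lives[0] == pytest.approx(122.2, rel=1e-3)

    def test_three_component_recovers_slowest_half_life(self):
        comps = default_components()
        series = make_series([[100.0, 50.0, 20.0]], components=comps)
        init = [c.half_life_s * f for c, f in zip(comps, (1.15, 0.85, 1.2))]
        res = fit_free_halflife(FRAME_TIMES, EXPOSURE, series.intensity[0],
                                3, init)
        assert res.success
        assert res.half_lives[-1] == pytest.approx(1222.0, rel=0.01)

    def test_zero_amplitude_component_flagged_unidentifiable(self):
        c = get_component("13N")
        series = make_series([[60.0]], components=[c])
        res = fit_free_halflife(FRAME_TIMES, EXPOSURE, series.intensity[0],
                                2, [550.0, 4000.0])
        assert not res.identifiable.all()
        # the identified component still matches 13N
        main = res.half_lives[res.identifiable]
        assert np.any(np.abs(main - 597.9) / 597.9 < 0.01)

    def test_bad_component_count_rejected(self):
        with pytest.raises(ValueError):
            fit_free_halflife(FRAME_TIMES, EXPOSURE, np.ones_like(FRAME_TIMES),
                              4, [1, 2, 3, 4])


class TestResolvedProfiles:
    def test_reconstruction_matches_fit_model(self):
        """Sum of resolved profiles x basis reproduces the fitted curve."""
        amps = np.array([[100.0, 50.0, 20.0], [30.0, 10.0, 5.0]])
        series = make_series(amps)
        comps = default_components()
        fit = fit_fixed_lambda(series, comps)
        resolved = resolve_component_profiles(fit)
        x = exposure_integrated_basis(comps, FRAME_TIMES, EXPOSURE)
        model = np.stack([resolved.profiles[c.isotope] for c in comps], axis=1) @ x.T
        assert np.allclose(model, series.intensity, rtol=1e-8)

    def test_closed_loop_profiles_within_two_sigma(self, noisy_sim):
        """Resolved profiles on a noisy rendered stack agree with the
        generator's blurred truth amplitudes within 2 sigma almost everywhere."""
        from cherenkov_xsec.pipeline import preprocess_stack

        sim = noisy_sim
        stack = sim.stack
        series = preprocess_stack(
            stack.frames, stack.frame_times, stack.exposure, stack.pixel_pitch,
            sim.dark_frames, read_noise_sigma=stack.read_noise_sigma,
            median_window=1, beam_fwhm_cm=sim.beam.lateral_fwhm[1],
        )
        fit = fit_fixed_lambda(series, sim.components)
        resolved = resolve_component_profiles(fit)
        ok = ~resolved.mask
        for comp in sim.components:
            iso = comp.isotope
            truth = stack.truth_amplitudes[iso][ok]
            z = (resolved.profiles[iso][ok] - truth) / resolved.sigmas[iso][ok]
            assert np.mean(np.abs(z) <= 2.0) >= 0.90
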