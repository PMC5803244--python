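"""Generator: activation equations, frame rendering, PET-side truth."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cherenkov_xsec.cherenkov import build_blur_kernel, cherenkov_yield_factor
from cherenkov_xsec.nuclides import default_components, get_component
from cherenkov_xsec.physics import BeamSpec, build_energy_depth_map, get_material
from cherenkov_xsec.synthetic import (
    CCDConfig,
    TruthXsecModel,
    XsecShape,
    activity_after_irradiation,
    default_truth,
    production_rate_profile,
    render_cherenkov_stack,
    render_pet_truth,
    simulate_experiment,
)


class _ConstantSigma:
    """sigma(E) = const above a floor energy, for analytic checks."""

    def __init__(self, value, floor=0.5):
        self.value, self.floor = value, floor

    def sigma(self, e):
        e = np.asarray(e, dtype=float)
        return np.where(e > self.floor, self.value, 0.0)


@pytest.fixture(scope="module")
def emap(quartz, reference_beam):
    return build_energy_depth_map(quartz, reference_beam, 0.0133, max_depth=3.5)


@pytest.fixture(scope="module")
def render_setup(quartz):
    comps = default_components()
    ccd = CCDConfig(n_lateral=16, frame_times=np.arange(120.0, 620.0, 5.0))
    beam = BeamSpec(72.0, 30.0, 1800.0)
    kernels = {c.isotope: build_blur_kernel(c, quartz, ccd.pixel_pitch, 64)
               for c in comps}
    yields = {c.isotope: cherenkov_yield_factor(c, quartz) for c in comps}
    return comps, ccd, beam, kernels, yields


@pytest.fixture(scope="module")
def pet_activities():
    comps = default_components()
    z = (np.arange(50) + 0.5) * 0.0133
    act = {c.isotope: 1e4 * np.exp(-0.5 * ((z - 0.3) / 0.1) ** 2) for c in comps}
    return comps, z, act


class TestProductionProfile:
    def test_zero_sigma_gives_zero(self, emap, quartz, reference_beam):
        truth = TruthXsecModel(shapes={"15O": _ConstantSigma(0.0)})
        rates = production_rate_profile(truth, emap, reference_beam, quartz)
        assert np.all(rates["15O"] == 0)

    def test_flat_sigma_no_attenuation_is_flat_to_range(self, emap, quartz, reference_beam):
        truth = TruthXsecModel(shapes={"15O": _ConstantSigma(50.0)})
        rates = production_rate_profile(truth, emap, reference_beam, quartz,
                                        removal_cross_section_barn=0.0)
        r = rates["15O"]
        live = emap.energy_at_depth > 0
        assert np.allclose(r[live], r[live][0], rtol=1e-12)
        assert np.all(r[~live] == 0)

    def test_linear_in_current(self, emap, quartz):
        truth = default_truth()
        b1 = BeamSpec(72.0, 30.0, 1800.0)
        b2 = BeamSpec(72.0, 60.0, 1800.0)
        r1 = production_rate_profile(truth, emap, b1, quartz)
        r2 = production_rate_profile(truth, emap, b2, quartz)
        for iso in r1:
            assert np.allclose(r2[iso], 2.0 * r1[iso], rtol=1e-12)

    def test_oxygen_free_material_rejected(self, emap, polyethylene, reference_beam):
        with pytest.raises(ValueError, match="no oxygen"):
            production_rate_profile(default_truth(), emap, reference_beam, polyethylene)


class TestActivation:
    def test_saturation_limit(self):
        c = get_component("15O")
        assert activity_after_irradiation(10.0, c, 1e9, 0.0) == pytest.approx(10.0)

    def test_half_life_halves_activity(self):
        c = get_component("11C")
        a0 = activity_after_irradiation(5.0, c, 1800.0, 0.0)
        a1 = activity_after_irradiation(5.0, c, 1800.0, c.half_life_s)
        assert a1 == pytest.approx(a0 / 2.0, rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            activity_after_irradiation(1.0, get_component("15O"), 100.0, -1.0)

    @pytest.mark.parametrize("iso", ["15O", "13N", "11C"])
    def test_matches_ode_integration(self, iso):
        """Closed form equals numerical integration of the build-up/decay ODE."""
        c = get_component(iso)
        rate, t_irr = 7.5, 1800.0
        lam = c.decay_constant
        build = solve_ivp(lambda t, n: rate - lam * n, (0, t_irr), [0.0],
                          rtol=1e-11, atol=1e-12, dense_output=True)
        n_end = build.y[0, -1]
        for t in [0.0, 60.0, 600.0, 3600.0]:
            decay = solve_ivp(lambda s, n: -lam * n, (0, max(t, 1e-9)), [n_end],
                              rtol=1e-11, atol=1e-14)
            expected_activity = lam * decay.y[0, -1]
            got = activity_after_irradiation(rate, c, t_irr, t)
            assert got == pytest.approx(expected_activity, rel=1e-8)


class TestRenderCherenkov:
    def test_zero_activity_is_dark_plus_noise(self, render_setup):
        comps, ccd, beam, kernels, yields = render_setup
        act = {c.isotope: np.zeros(64) for c in comps}
        stack = render_cherenkov_stack(act, comps, ccd, kernels, yields, beam, seed=5)
        assert stack.frames.mean() == pytest.approx(ccd.dark_level, abs=1.0)

    def test_noise_free_delta_traces_kernel(self, render_setup):
        comps, ccd, beam, kernels, yields = render_setup
        iso = "11C"
        act = {iso: np.zeros(64)}
        act[iso][30] = 1e6
        stack = render_cherenkov_stack(act, [c for c in comps if c.isotope == iso],
                                       ccd, kernels, yields, beam, noise=False)
        profile = stack.frames[0].astype(float).sum(axis=0) - ccd.n_lateral * ccd.dark_level
        kern = kernels[iso].kernel
        half = len(kern) // 2
        expected = np.zeros(64)
        expected[30 - half:30 + half + 1] = kern
        expected *= profile.sum()
        assert np.allclose(profile, expected, atol=0.02 * profile.max())

    def test_seeded_reproducibility(self, render_setup):
        comps, ccd, beam, kernels, yields = render_setup
        act = {c.isotope: np.full(64, 1e5) for c in comps}
        s1 = render_cherenkov_stack(act, comps, ccd, kernels, yields, beam, seed=42)
        s2 = render_cherenkov_stack(act, comps, ccd, kernels, yields, beam, seed=42)
        assert np.array_equal(s1.frames, s2.frames)

    def test_negative_frame_start_rejected(self, render_setup):
        comps, ccd, beam, kernels, yields = render_setup
        with pytest.raises(ValueError):
            CCDConfig(frame_times=np.array([-5.0, 0.0, 5.0]))


class TestLateDecaySlope:
    def test_late_light_curve_decays_at_11c_rate(self, quartz):
        """After 3000 s the total light decays at the 11C decay constant."""
        comps = default_components()
        ccd = CCDConfig(n_lateral=8, frame_times=np.arange(3000.0, 3600.0, 5.0))
        beam = BeamSpec(72.0, 30.0, 1800.0)
        kernels = {c.isotope: build_blur_kernel(c, quartz, ccd.pixel_pitch, 64)
                   for c in comps}
        yields = {c.isotope: cherenkov_yield_factor(c, quartz) for c in comps}
        act = {c.isotope: (np.full(64, 1e6) if c.isotope == "11C" else np.zeros(64))
               for c in comps}
        stack = render_cherenkov_stack(act, comps, ccd, kernels, yields, beam,
                                       noise=False)
        totals = stack.frames.astype(float).sum(axis=(1, 2)) \
            - ccd.dark_level * stack.frames[0].size
        t = stack.frame_times + ccd.exposure / 2.0
        lam_fit = -np.polyfit(t, np.log(totals), 1)[0]
        lam_11c = get_component("11C").decay_constant
        assert lam_fit == pytest.approx(lam_11c, rel=0.02)

    def test_mixture_slope_bracketed_by_component_rates(self, quartz):
        """A late-time 13N + 11C mixture decays between the two pure rates."""
        comps = [get_component("13N"), get_component("11C")]
        ccd = CCDConfig(n_lateral=8, frame_times=np.arange(3000.0, 3600.0, 5.0))
        beam = BeamSpec(72.0, 30.0, 1800.0)
        kernels = {c.isotope: build_blur_kernel(c, quartz, ccd.pixel_pitch, 64)
                   for c in comps}
        yields = {c.isotope: cherenkov_yield_factor(c, quartz) for c in comps}
        act = {c.isotope: np.full(64, 1e6) for c in comps}
        stack = render_cherenkov_stack(act, comps, ccd, kernels, yields, beam,
                                       noise=False)
        totals = stack.frames.astype(float).sum(axis=(1, 2)) \
            - ccd.dark_level * stack.frames[0].size
        lam_fit = -np.polyfit(stack.frame_times, np.log(totals), 1)[0]
        assert get_component("11C").decay_constant < lam_fit
        assert lam_fit < get_component("13N").decay_constant


class TestPetTruth:
    def test_zero_width_window_is_zero(self, pet_activities):
        comps, z, act = pet_activities
        p = render_pet_truth(act, comps, z, (100.0, 100.0))
        assert np.all(p.positrons == 0)

    def test_total_counts_conserved_over_all_time(self, pet_activities):
        """All atoms present at t=0 eventually decay: counts over (0, inf)
        with the PSF off equal N_0 x branching."""
        comps, z, act = pet_activities
        p = render_pet_truth(act, comps, z, (0.0, 1e9), psf_fwhm=0.0)
        expected = sum(
            (act[c.isotope] / c.decay_constant * c.branching_ratio).sum()
            for c in comps
        )
        assert p.positrons.sum() == pytest.approx(expected, rel=1e-9)

    def test_disjoint_windows_sum_to_union(self, pet_activities):
        comps, z, act = pet_activities
        p1 = render_pet_truth(act, comps, z, (100.0, 400.0))
        p2 = render_pet_truth(act, comps, z, (400.0, 900.0))
        pu = render_pet_truth(act, comps, z, (100.0, 900.0))
        assert np.allclose(p1.positrons + p2.positrons, pu.positrons, rtol=1e-12)

    def test_invalid_window_rejected(self, pet_activities):
        comps, z, act = pet_activities
        with pytest.raises(ValueError):
            render_pet_truth(act, comps, z, (500.0, 100.0))


class TestDefaultTruthShapes:
    def test_thresholds_and_orderings(self):
        truth = default_truth()
        e = np.linspace(1, 72, 1000)
        s15 = truth.sigma("15O", e)
        assert np.all(s15[e <= 16.6] == 0)
        peak_e = e[np.argmax(s15)]
        assert 33.0 < peak_e < 37.0
        # 13N resonance structure below 20 MeV
        s13 = truth.sigma("13N", e)
        assert s13[(e > 10) & (e < 20)].max() > s13[(e > 20) & (e < 30)].max()
        # 11C opens near 30 and rises through 30-45 MeV
        s11 = truth.sigma("11C", e)
        assert np.all(s11[e <= 27.5] == 0)
        assert s11[np.argmin(np.abs(e - 45))] > s11[np.argmin(np.abs(e - 32))]

    def test_sigma_nonnegative(self):
        truth = default_truth()
        e = np.linspace(0.1, 100, 500)
        for iso in truth.isotopes:
            assert np.all(truth.sigma(iso, e) >= 0)


class TestCountingConservation:
    def test_atoms_produced_equal_atoms_decayed(self, noiseless_sim):
        """Per depth bin: R x saturation / lambda atoms at t=0 all decay."""
        sim = noiseless_sim
        for comp in sim.components:
            iso = comp.isotope
            lam = comp.decay_constant
            n0 = sim.rates[iso] * (-np.expm1(-lam * sim.beam.irradiation_duration)) / lam
            p = render_pet_truth(
                {iso: sim.stack.truth_activity_t0[iso]}, [comp],
                sim.emap.depth_grid, (0.0, 1e8), psf_fwhm=0.0,
            )
            assert np.allclose(p.positrons, n0 * comp.branching_ratio, rtol=1e-6)
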