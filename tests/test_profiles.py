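"""Radial profiles, Wilson fits, ensembles and B-matching."""

import numpy as np
import pytest

from emsharp.grids import VoxelGrid
from emsharp.models import Atom, AtomicModel
from emsharp.profiles import (RadialProfile, average_profiles, debye_peak,
                              match_profile_b, radial_profile, read_profile,
                              wilson_fit, write_profile)
from emsharp.simulate import SimulationConfig, apply_b_factor, model_to_map


class TestRadialProfile:
    def test_point_scatterer_gives_flat_spectrum(self):
        values = np.zeros((32, 32, 32))
        values[16, 16, 16] = 1.0
        profile = radial_profile(VoxelGrid(values, 1.0))
        assert np.allclose(profile.amplitudes, profile.amplitudes[0],
                           rtol=1e-9)

    def test_gaussian_matches_closed_form(self):
        """An isotropic Gaussian's spectrum is the analytic Gaussian
        transform, shell-averaged with the same binning, within 1%."""
        from emsharp.profiles import shell_bins
        n, vox, sigma = 48, 1.0, 2.0
        x = (np.arange(n) - n // 2) * vox
        r2 = (x[:, None, None] ** 2 + x[None, :, None] ** 2
              + x[None, None, :] ** 2)
        values = np.exp(-r2 / (2 * sigma**2))
        profile = radial_profile(VoxelGrid(values, vox))
        # closed-form |FT| at every Fourier voxel, averaged per shell
        index, weights, centres = shell_bins((n, n, n), vox)
        sx = np.fft.fftfreq(n, vox)
        sz = np.fft.rfftfreq(n, vox)
        s2 = sx[:, None, None]**2 + sx[None, :, None]**2 + sz[None, None, :]**2
        analytic = (2 * np.pi * sigma**2) ** 1.5 * np.exp(
            -2 * np.pi**2 * sigma**2 * s2)
        wsum = np.bincount(index.ravel(), weights.ravel(),
                           minlength=len(centres))
        asum = np.bincount(index.ravel(), (weights * analytic).ravel(),
                           minlength=len(centres))
        expected = asum[wsum > 0] / wsum[wsum > 0]
        expected = expected[:len(profile.amplitudes)]
        # compare where the signal is above the periodic-aliasing floor
        sel = expected > 1e-6 * expected[0]
        assert np.allclose(profile.amplitudes[sel] / expected[sel], 1.0,
                           atol=0.01)

    def test_counts_cover_the_nyquist_sphere(self):
        grid = VoxelGrid(np.random.default_rng(0).normal(size=(24, 24, 24)),
                         1.0)
        profile = radial_profile(grid)
        # voxels inside the Nyquist ball ~ (pi/6) * N^3, shell-quantized
        assert profile.counts.sum() <= 24**3
        assert profile.counts.sum() > 0.9 * np.pi / 6 * 24**3

    def test_too_many_shells_rejected(self):
        grid = VoxelGrid(np.ones((16, 16, 16)), 1.0)
        with pytest.raises(ValueError, match="finer"):
            radial_profile(grid, n_shells=100)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            radial_profile(VoxelGrid(np.zeros((8, 8, 8)), 1.0))


class TestWilsonFit:
    def test_exact_line_recovered(self):
        s = np.linspace(0.02, 0.5, 60)
        profile = RadialProfile(s, np.exp(2.0 - 200.0 * s**2 / 4))
        fit = wilson_fit(profile)
        assert fit.b_wilson == pytest.approx(200.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(2.0, abs=1e-9)

    def test_paired_simulations_recover_delta_b(self, small_helix):
        """Form-factor fall-off cancels in the difference of paired fits."""
        cfg = SimulationConfig(box_edge=48.0, voxel_size=1.0)
        fits = []
        for b in (0.0, 100.0):
            model = small_helix.with_b_factors(np.full(len(small_helix), b))
            fits.append(wilson_fit(radial_profile(model_to_map(model, cfg))))
        assert fits[1].b_wilson - fits[0].b_wilson == pytest.approx(100.0,
                                                                   abs=5.0)

    def test_including_debye_band_degrades_fit(self):
        """A modulation confined to 6.5-3.5 Å leaves the excluded fit
        perfect but contaminates the all-shell fit."""
        s = np.linspace(0.05, 0.5, 60)
        # compact modulation strictly inside the 6.5-3.5 Å band
        lo, hi = 1 / 6.5, 1 / 3.5
        t = np.clip((s - lo) / (hi - lo), 0, 1)
        bump = 0.4 * np.sin(np.pi * t) ** 2 * ((s > lo) & (s < hi))
        profile = RadialProfile(s, np.exp(1.0 - 150.0 * s**2 / 4 + bump))
        clean = wilson_fit(profile, exclude_band=(6.5, 3.5))
        contaminated = wilson_fit(profile, exclude_band=None)
        assert clean.r_squared == pytest.approx(1.0, abs=1e-10)
        assert contaminated.r_squared < clean.r_squared - 1e-4
        assert clean.b_wilson == pytest.approx(150.0, abs=1e-6)

    def test_scale_invariance(self, small_helix_map):
        profile = radial_profile(small_helix_map)
        fit = wilson_fit(profile)
        fit_scaled = wilson_fit(profile.scaled(37.0))
        assert fit_scaled.slope == pytest.approx(fit.slope, rel=1e-9)
        assert fit_scaled.intercept == pytest.approx(
            fit.intercept + np.log(37.0), rel=1e-9)

    def test_nonpositive_amplitudes_rejected(self):
        s = np.linspace(0.1, 0.5, 20)
        amp = np.ones_like(s)
        amp[10] = 0.0
        with pytest.raises(ValueError, match="onpositive"):
            wilson_fit(RadialProfile(s, amp))

    def test_too_few_shells_rejected(self):
        s = np.array([0.2, 0.3, 0.4])
        with pytest.raises(ValueError, match="5"):
            wilson_fit(RadialProfile(s, np.ones(3)))


def test_b_dampening_commutes_with_shell_averaging(small_helix_map):
    """The profile of a blurred map equals the dampened-amplitude shell
    average of the original, computed independently voxel by voxel."""
    from emsharp.grids import fourier_transform
    from emsharp.profiles import shell_bins
    b = 120.0
    p1 = radial_profile(apply_b_factor(small_helix_map, b))
    fv = fourier_transform(small_helix_map)
    damped = np.abs(fv.coefficients) * np.exp(-b * fv.frequency_grid**2 / 4)
    index, weights, centres = shell_bins(fv.shape, fv.voxel_size)
    wsum = np.bincount(index.ravel(), weights.ravel(), minlength=len(centres))
    asum = np.bincount(index.ravel(), (weights * damped).ravel(),
                       minlength=len(centres))
    expected = (asum[wsum > 0] / wsum[wsum > 0])[:len(p1.amplitudes)]
    sel = expected > 1e-12 * expected.max()
    assert np.allclose(p1.amplitudes[sel], expected[sel], rtol=1e-6)


class TestAverageProfiles:
    def test_identical_members_have_zero_sigma(self, small_helix_map):
        p = radial_profile(small_helix_map)
        ens = average_profiles([p, p, p], label="alpha")
        assert np.allclose(ens.mean, p.amplitudes)
        assert np.allclose(ens.sigma, 0.0)
        assert ens.n_members == 3

    def test_two_member_mean_by_hand(self):
        s = np.array([0.1, 0.2, 0.3])
        a = RadialProfile(s, np.array([4.0, 2.0, 1.0]))
        b = RadialProfile(s, np.array([2.0, 6.0, 3.0]))
        ens = average_profiles([a, b])
        assert np.allclose(ens.mean, [3.0, 4.0, 2.0])
        assert np.allclose(ens.sigma, [1.0, 2.0, 1.0])

    def test_members_truncated_to_common_range(self):
        a = RadialProfile(np.linspace(0.05, 0.5, 20), np.ones(20))
        b = RadialProfile(np.linspace(0.1, 0.4, 10), 2 * np.ones(10))
        ens = average_profiles([a, b])
        assert ens.frequencies.min() >= 0.1 - 1e-9
        assert ens.frequencies.max() <= 0.4 + 1e-9
        assert np.allclose(ens.mean, 1.5)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_profiles([])


class TestMatchProfileB:
    def test_matching_to_own_b_is_identity(self, small_helix_map):
        p = radial_profile(small_helix_map)
        b_own = wilson_fit(p).b_wilson
        out = match_profile_b(p, b_own)
        assert np.allclose(out.amplitudes, p.amplitudes, rtol=1e-9)

    def test_refit_returns_target(self, small_helix_map):
        p = radial_profile(small_helix_map)
        out = match_profile_b(p, 50.0)
        assert wilson_fit(out).b_wilson == pytest.approx(50.0, abs=2.0)


class TestWilsonFitProperties:
    """Property-based invariants of the Guinier fit."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=400.0),
           st.floats(min_value=-3.0, max_value=3.0))
    def test_exact_wilson_lines_are_recovered(self, b, log_scale):
        s = np.linspace(0.05, 0.5, 40)
        profile = RadialProfile(s, np.exp(log_scale - b * s**2 / 4))
        fit = wilson_fit(profile)
        assert fit.b_wilson == pytest.approx(b, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(min_value=10.0, max_value=300.0))
    def test_matching_composes_to_the_target(self, b_target):
        s = np.linspace(0.05, 0.5, 40)
        profile = RadialProfile(s, np.exp(1.0 - 120.0 * s**2 / 4))
        out = match_profile_b(profile, b_target)
        assert wilson_fit(out).b_wilson == pytest.approx(b_target, abs=1e-6)


def test_profile_serialization_round_trip(tmp_path, small_helix_map):
    p = radial_profile(small_helix_map)
    path = tmp_path / "profile.tsv"
    write_profile(p, path, metadata={"label": "alpha"})
    back = read_profile(path)
    assert np.allclose(back.frequencies, p.frequencies)
    assert np.allclose(back.amplitudes, p.amplitudes)
    assert np.allclose(back.counts, p.counts)


def test_helix_debye_peak_near_4p5(small_helix_map):
    """Even a short ideal helix shows the pitch-related maximum."""
    d_peak, prominence = debye_peak(radial_profile(small_helix_map))
    assert 4.0 <= d_peak <= 5.2
    assert prominence > 0
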