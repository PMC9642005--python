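"""Global sharpening, per-window amplitude scaling, rolling-window local
scaling and windowed local-B estimation."""

import numpy as np
import pytest

from emsharp.grids import VoxelGrid
from emsharp.fixtures import build_two_domain_phantom
from emsharp.perturb import build_model_mask
from emsharp.profiles import (RadialProfile, profile_from_fourier,
                              radial_profile, shell_bins, wilson_fit)
from emsharp.grids import fourier_transform
from emsharp.sharpen import (LocalBMap, ScalingConfig, local_b_map, locscale,
                             locscale_model_free, scale_amplitudes,
                             sharpen_global)
from emsharp.simulate import SimulationConfig, apply_b_factor, model_to_map


@pytest.fixture(scope="module")
def helix_setup(small_helix_map_module=None):
    from emsharp.fixtures import FragmentSpec, build_helix
    helix = build_helix(FragmentSpec("alpha", "A" * 12, b_iso=30.0))
    cfg = SimulationConfig(box_edge=40.0, voxel_size=1.0)
    grid = model_to_map(helix, cfg)
    mask = build_model_mask(helix, grid, dilation=2.0, edge_width=3)
    return helix, grid, mask


class TestSharpenGlobal:
    def test_zero_b_is_identity(self, helix_setup):
        _, grid, _ = helix_setup
        out = sharpen_global(grid, 0.0)
        assert np.allclose(out.values, grid.values,
                           atol=1e-12 * np.abs(grid.values).max())

    def test_inverse_pair_restores(self, helix_setup):
        """Blurring by +B then sharpening with -B recovers the map."""
        _, grid, _ = helix_setup
        out = sharpen_global(apply_b_factor(grid, 100.0), -100.0)
        rms = np.sqrt(np.mean((out.values - grid.values) ** 2))
        assert rms / np.std(grid.values) < 1e-6

    def test_sharpening_boosts_high_frequency_contrast(self, helix_setup):
        """Negative B never decreases the high/low shell amplitude ratio."""
        _, grid, _ = helix_setup
        def ratio(g):
            p = radial_profile(g)
            lo = p.amplitudes[(p.frequencies > 0) & (p.frequencies <= 0.2)]
            hi = p.amplitudes[p.frequencies > 0.35]
            return hi.sum() / lo.sum()
        assert ratio(sharpen_global(grid, -80.0)) > ratio(grid)


class TestScaleAmplitudes:
    def test_self_reference_is_identity(self, helix_setup):
        _, grid, _ = helix_setup
        own = radial_profile(grid)
        out = scale_amplitudes(grid, own)
        assert np.allclose(out.values, grid.values,
                           atol=1e-9 * np.abs(grid.values).max())

    def test_profile_conformance_shell_wise(self, helix_setup):
        """After scaling, the window's profile equals the reference on
        every shell above the amplitude floor."""
        _, grid, _ = helix_setup
        target = radial_profile(apply_b_factor(grid, -60.0))
        out = scale_amplitudes(apply_b_factor(grid, 90.0), target)
        got = radial_profile(out)
        n = min(len(got), len(target))
        assert np.allclose(got.amplitudes[1:n], target.amplitudes[1:n],
                           rtol=1e-6)

    def test_zero_window_returned_unchanged(self):
        zero = VoxelGrid(np.zeros((16, 16, 16)), 1.0)
        ref = RadialProfile(np.linspace(0.0, 0.5, 9), np.ones(9))
        out = scale_amplitudes(zero, ref)
        assert np.all(out.values == 0.0)


class TestLocscale:
    def test_self_reference_identity_on_masked_voxels(self, helix_setup):
        _, grid, mask = helix_setup
        config = ScalingConfig(window_size=12.0, mask=mask)
        out = locscale(grid, grid, config)
        sel = mask.values > 0.5
        assert np.allclose(out.values[sel], grid.values[sel],
                           atol=1e-9 * np.abs(grid.values).max())
        assert np.all(out.values[~sel] == 0.0)

    def test_passthrough_outside_mask(self, helix_setup):
        _, grid, mask = helix_setup
        config = ScalingConfig(window_size=12.0, mask=mask,
                               outside="passthrough")
        out = locscale(grid, grid, config)
        sel = mask.values > 0.5
        assert np.allclose(out.values[~sel], grid.values[~sel])

    def test_restores_windowed_wilson_b(self):
        """Scaling a blurred map against the sharp reference restores most
        of the reference's windowed fall-off."""
        from emsharp.fixtures import FragmentSpec, build_helix
        helix = build_helix(FragmentSpec("alpha", "A" * 12, b_iso=30.0))
        cfg = SimulationConfig(box_edge=48.0, voxel_size=1.0)
        grid = model_to_map(helix, cfg)
        mask = build_model_mask(helix, grid, dilation=2.0, edge_width=3)
        blurred = apply_b_factor(grid, 150.0)
        out = locscale(blurred, grid,
                       ScalingConfig(window_size=16.0, mask=mask))
        # estimate local B with tapered windows over shells above the
        # leakage floor (no Debye exclusion for a poly-Ala fragment)
        est = ScalingConfig(window_size=24.0, mask=mask, stride=2,
                            taper=True, wilson_range=(10.0, 0.3),
                            debye_band=None)

        def median_b(g):
            lbm = local_b_map(g, est)
            return np.median(lbm.b_values[np.isfinite(lbm.b_values)])

        b_ref, b_blur, b_out = median_b(grid), median_b(blurred), median_b(out)
        assert b_blur > b_ref + 100.0
        assert abs(b_out - b_ref) < 0.4 * abs(b_blur - b_ref)

    def test_grid_mismatch_rejected(self, helix_setup):
        _, grid, _ = helix_setup
        other = VoxelGrid(np.ones((16, 16, 16)), 1.0)
        with pytest.raises(ValueError, match="identical grid"):
            locscale(grid, other)

    def test_signal_outside_mask_dampened_by_model_reference(self):
        """A point source more than half a window beyond the reference
        envelope loses at least half its amplitude after scaling."""
        from emsharp.models import Atom, AtomicModel
        cfg = SimulationConfig(box_edge=40.0, voxel_size=1.0)
        origin = np.array([-20.0, -20.0, -20.0])
        model = AtomicModel([Atom("C", [-8.0, 0.0, 0.0], b_iso=20.0)])
        stray = AtomicModel([Atom("C", [10.0, 0.0, 0.0], b_iso=20.0)])
        reference = model_to_map(model, cfg, origin=origin)
        observed = model_to_map(AtomicModel(model.atoms + stray.atoms), cfg,
                                origin=origin)
        # scale everywhere so the stray's position is evaluated too
        config = ScalingConfig(window_size=12.0)
        out = locscale(observed, reference, config)
        stray_idx = tuple(np.rint((stray.atoms[0].position - origin)).astype(int))
        assert out.values[stray_idx] < 0.5 * observed.values[stray_idx]


class TestLocscaleModelFree:
    def test_uniform_map_reduces_to_global_case(self, helix_setup):
        """With the map's own profile as reference and its fitted B as
        target, model-free scaling is a per-window identity."""
        _, grid, mask = helix_setup
        p = radial_profile(grid)
        from emsharp.profiles import ProfileEnsemble
        ens = ProfileEnsemble(p.frequencies, p.amplitudes,
                              np.zeros(len(p)), 1, "alpha")
        b_own = wilson_fit(p).b_wilson
        config = ScalingConfig(window_size=14.0, mask=mask)
        out = locscale_model_free(grid, ens, b_own, config)
        sel = mask.values > 0.5
        assert np.corrcoef(out.values[sel], grid.values[sel])[0, 1] > 0.98

    def test_undefined_target_b_leaves_window_unscaled(self, helix_setup):
        _, grid, mask = helix_setup
        p = radial_profile(grid)
        from emsharp.profiles import ProfileEnsemble
        ens = ProfileEnsemble(p.frequencies, p.amplitudes,
                              np.zeros(len(p)), 1, "alpha")
        undefined = LocalBMap(np.full(grid.values.shape, np.nan),
                              np.full(grid.values.shape, np.nan),
                              grid.voxel_size)
        config = ScalingConfig(window_size=14.0, mask=mask)
        out = locscale_model_free(grid, ens, undefined, config)
        sel = mask.values > 0.5
        assert np.allclose(out.values[sel], grid.values[sel],
                           atol=1e-9 * np.abs(grid.values).max())


class TestLocalBMap:
    def test_uniform_b_map_is_homogeneous(self, helix_setup):
        helix, _, _ = helix_setup
        cfg = SimulationConfig(box_edge=40.0, voxel_size=1.0)
        grid = model_to_map(helix.with_b_factors(
            np.full(len(helix), 80.0)), cfg)
        mask = build_model_mask(helix, grid, dilation=1.5, edge_width=2)
        config = ScalingConfig(window_size=16.0, mask=mask, stride=2)
        lbm = local_b_map(grid, config)
        vals = lbm.b_values[np.isfinite(lbm.b_values)]
        assert len(vals) > 10
        assert vals.std() < 10.0

    def test_two_domain_phantom_separates(self):
        """Windowed Wilson fits resolve a 50 vs 300 Å² domain contrast."""
        phantom = build_two_domain_phantom(50.0, 300.0, separation=40.0,
                                           n_residues=12)
        cfg = SimulationConfig(box_edge=88.0, voxel_size=1.0)
        grid = model_to_map(phantom, cfg)
        mask = build_model_mask(phantom, grid, dilation=2.0, edge_width=2)
        # tapered windows and a fit capped at d = 3.3 Å keep the B = 300
        # domain's shells above the spectral-leakage floor
        config = ScalingConfig(window_size=25.0, mask=mask, stride=4,
                               taper=True, wilson_range=(10.0, 0.3),
                               debye_band=None)
        lbm = local_b_map(grid, config)
        xs = grid.origin[0] + np.arange(grid.values.shape[0])
        split = xs.mean()
        low = lbm.b_values[xs < split][np.isfinite(lbm.b_values[xs < split])]
        high = lbm.b_values[xs >= split][
            np.isfinite(lbm.b_values[xs >= split])]
        sep = np.median(high) - np.median(low)
        assert sep == pytest.approx(250.0, abs=60.0)
        r2 = lbm.r_squared[np.isfinite(lbm.r_squared)]
        assert np.all((r2 >= 0.0) & (r2 <= 1.0 + 1e-12))
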