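import numpy as np
import pytest

from leafspec.pls import FittedModel
from leafspec.preprocessing import PreprocessRecipe
from leafspec.synthetic import SimulationConfig, generate_cube
from leafspec.visualization import (
    ConcentrationMap,
    LeeParams,
    enhanced_lee,
    invert_pixels,
    render_pseudocolor,
    segment_leaf,
    value_from_color,
)


@pytest.fixture(scope="module")
def noise_free_cfg():
    return SimulationConfig(n_bands=200, noise_sd=0.0, drift_sd=0.0, scatter_sd=0.0, seed=2)


def _leaf_map(value=10.0, shape=(12, 12)):
    cmap = np.zeros(shape)
    cmap[2:-2, 2:-2] = value
    return cmap


def _fit_inversion_model(cfg, recipe_steps="none"):
    """Train a PLSR model on forward-simulated spectra from the same config."""
    from leafspec.pls import fit_plsr
    from leafspec.synthetic import generate_dataset

    ds_cfg = SimulationConfig(
        n_samples=120,
        n_bands=cfg.n_bands,
        noise_sd=0.0,
        drift_sd=0.0,
        scatter_sd=0.0,
        seed=17,
    )
    spectra, truth = generate_dataset(ds_cfg)
    recipe = PreprocessRecipe(recipe_steps)
    X = recipe.apply(spectra.values)
    y = truth.concentrations["chla"]
    return fit_plsr(
        X, y, n_latent=6, wavelengths=spectra.wavelengths, recipe=recipe, pigment="chla"
    )


class TestSegmentLeaf:
    def test_recovers_generator_mask(self, noise_free_cfg):
        cube = generate_cube(noise_free_cfg, _leaf_map())
        mask = segment_leaf(cube.reflectance)
        np.testing.assert_array_equal(mask, cube.mask)

    def test_all_background_errors(self, noise_free_cfg):
        cube = generate_cube(noise_free_cfg, np.zeros((6, 6)))
        with pytest.raises(ValueError):
            segment_leaf(cube.reflectance)

    def test_threshold_one_errors(self, noise_free_cfg):
        cube = generate_cube(noise_free_cfg, _leaf_map())
        with pytest.raises(ValueError):
            segment_leaf(cube.reflectance, threshold=1.0)

    def test_largest_component_kept(self, noise_free_cfg):
        cmap = np.zeros((14, 14))
        cmap[1:3, 1:3] = 5.0  # small blob
        cmap[5:13, 5:13] = 5.0  # large blob
        cube = generate_cube(noise_free_cfg, cmap)
        mask = segment_leaf(cube.reflectance)
        assert mask[8, 8] and not mask[1, 1]


class TestInvertPixels:
    def test_uniform_cube_recovers_concentration(self, noise_free_cfg):
        cube = generate_cube(noise_free_cfg, _leaf_map(value=12.0))
        model = _fit_inversion_model(noise_free_cfg)
        out = invert_pixels(cube.reflectance, model, cube.mask)
        fg = out.values[cube.mask]
        np.testing.assert_allclose(fg, 12.0, rtol=1e-6)

    def test_zero_coefficients_give_intercept(self, noise_free_cfg):
        cube = generate_cube(noise_free_cfg, _leaf_map())
        model = FittedModel(
            band_indices=np.array([0, 1]),
            wavelengths=cube.reflectance.wavelengths[:2],
            coefficients=np.zeros(2),
            intercept=7.5,
            n_latent=1,
        )
        out = invert_pixels(cube.reflectance, model, cube.mask)
        np.testing.assert_allclose(out.values[cube.mask], 7.5)

    def test_background_is_nan(self, noise_free_cfg):
        cube = generate_cube(noise_free_cfg, _leaf_map())
        model = _fit_inversion_model(noise_free_cfg)
        out = invert_pixels(cube.reflectance, model, cube.mask)
        assert np.isnan(out.values[~cube.mask]).all()

    def test_map_mean_matches_roi_mean_prediction_linear_recipe(self, noise_free_cfg):
        # linearity: mean of pixel predictions == prediction of mean spectrum
        # (holds for recipe none/SG, not SNV)
        cmap = _leaf_map(value=9.0)
        cmap[6:, :] *= 2.0
        cube = generate_cube(noise_free_cfg, cmap)
        model = _fit_inversion_model(noise_free_cfg, "sg")
        out = invert_pixels(cube.reflectance, model, cube.mask)
        pixels = cube.reflectance.data[cube.mask]
        mean_spec = model.recipe.apply(pixels.mean(axis=0)[None, :])
        pred_of_mean = model.predict_full(mean_spec)[0]
        assert np.nanmean(out.values) == pytest.approx(pred_of_mean, rel=1e-9)

    def test_missing_wavelength_errors(self, noise_free_cfg):
        cube = generate_cube(noise_free_cfg, _leaf_map())
        model = FittedModel(
            band_indices=np.array([0]),
            wavelengths=np.array([1500.0]),  # far outside the axis
            coefficients=np.array([1.0]),
            intercept=0.0,
            n_latent=1,
        )
        with pytest.raises(ValueError, match="not present"):
            invert_pixels(cube.reflectance, model, cube.mask)


class TestEnhancedLee:
    def test_constant_image_unchanged(self):
        cmap = ConcentrationMap(values=np.full((8, 8), 5.0))
        out = enhanced_lee(cmap)
        np.testing.assert_allclose(out.values, 5.0)

    def test_transition_zone_hand_computed(self):
        # 3x3 flat region of 1.0 with center 4.0: window mean and sd give
        # Ci in (0.52, 1.73) so the damped-weight branch applies
        vals = np.full((3, 3), 1.0)
        vals[1, 1] = 4.0
        w = vals.ravel()
        mean, sd = w.mean(), w.std(ddof=1)
        ci = sd / mean
        params = LeeParams()
        assert params.homogeneity < ci < params.heterogeneous
        weight = np.exp(-params.damping * (ci - params.homogeneity) / (params.heterogeneous - ci))
        expected_center = mean + weight * (4.0 - mean)
        out = enhanced_lee(ConcentrationMap(values=vals), params)
        assert out.values[1, 1] == pytest.approx(expected_center)
        assert abs(out.values[1, 1] - mean) < abs(4.0 - mean)  # attenuated

    def test_heterogeneous_zone_passthrough(self):
        vals = np.full((3, 3), 0.1)
        vals[1, 1] = 10.0  # extreme spike: CV >= 1.73 -> preserved
        ci = vals.std(ddof=1) / vals.mean()
        assert ci >= 1.73
        out = enhanced_lee(ConcentrationMap(values=vals))
        assert out.values[1, 1] == 10.0

    def test_mean_preserving_on_homogeneous_interior(self, rng):
        vals = 10.0 + 0.01 * rng.normal(size=(12, 12))
        out = enhanced_lee(ConcentrationMap(values=vals))
        interior = (slice(1, -1), slice(1, -1))
        assert out.values[interior].mean() == pytest.approx(vals[interior].mean(), abs=1e-3)

    def test_background_untouched(self):
        vals = np.full((5, 5), 3.0)
        vals[0, :] = np.nan
        out = enhanced_lee(ConcentrationMap(values=vals))
        assert np.isnan(out.values[0]).all()
        np.testing.assert_allclose(out.values[2], 3.0)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            LeeParams(window=4)
        with pytest.raises(ValueError):
            LeeParams(homogeneity=2.0, heterogeneous=1.0)


class TestRenderPseudocolor:
    def test_range_min_pure_blue_max_pure_red(self, tmp_path):
        cmap = ConcentrationMap(values=np.array([[0.0, 30.0]]), display_range=(0.0, 30.0))
        rgba = render_pseudocolor(cmap, out_path=tmp_path / "m.png")
        assert tuple(rgba[0, 0]) == (0, 0, 255, 255)  # blue
        assert tuple(rgba[0, 1]) == (255, 0, 0, 255)  # red
        assert (tmp_path / "m.png").exists()

    def test_background_transparent(self):
        cmap = ConcentrationMap(values=np.array([[np.nan, 15.0]]))
        rgba = render_pseudocolor(cmap)
        assert rgba[0, 0, 3] == 0
        assert rgba[0, 1, 3] == 255

    def test_roundtrip_within_lut_resolution(self, rng):
        values = rng.uniform(0.0, 30.0, size=(6, 6))
        cmap = ConcentrationMap(values=values, display_range=(0.0, 30.0))
        rgba = render_pseudocolor(cmap)
        for (r, c) in [(0, 0), (3, 4), (5, 5)]:
            recovered = value_from_color(rgba[r, c], (0.0, 30.0))
            assert recovered == pytest.approx(values[r, c], abs=30.0 / 255 + 1e-9)

    def test_out_of_range_clipped(self):
        cmap = ConcentrationMap(values=np.array([[-5.0, 50.0]]), display_range=(0.0, 30.0))
        rgba = render_pseudocolor(cmap)
        assert tuple(rgba[0, 0, :3]) == (0, 0, 255)
        assert tuple(rgba[0, 1, :3]) == (255, 0, 0)


class TestRoundTrip:
    def test_two_level_forward_inverse_noise_free(self, noise_free_cfg):
        cmap = np.zeros((12, 12))
        cmap[2:6, 2:10] = 5.0
        cmap[7:11, 2:10] = 20.0
        cube = generate_cube(noise_free_cfg, cmap)
        model = _fit_inversion_model(noise_free_cfg)
        out = invert_pixels(cube.reflectance, model, cube.mask)
        low = out.values[2:6, 2:10].mean()
        high = out.values[7:11, 2:10].mean()
        assert low == pytest.approx(5.0, rel=1e-6)
        assert high == pytest.approx(20.0, rel=1e-6)

    def test_two_level_forward_inverse_with_noise(self):
        cfg = SimulationConfig(n_bands=200, noise_sd=0.01, seed=6)
        cmap = np.zeros((14, 14))
        cmap[2:7, 2:12] = 5.0
        cmap[8:13, 2:12] = 20.0
        cube = generate_cube(cfg, cmap)
        model = _fit_inversion_model(cfg)
        out = invert_pixels(cube.reflectance, model, cube.mask)
        out = enhanced_lee(out)
        assert out.values[2:7, 2:12].mean() == pytest.approx(5.0, rel=0.10)
        assert out.values[8:13, 2:12].mean() == pytest.approx(20.0, rel=0.10)
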