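"""Pixel-wise prediction consistency, segmentation, and rendering purity."""

import numpy as np
import pytest

from brixmap import (
    ModelBundle,
    SpectraTable,
    SynthConfig,
    extract_mean_spectra,
    fit_plsr,
    fit_svr,
    SVRParams,
    generate_cube,
)
from brixmap.errors import MappingError, RenderError, SegmentationError
from brixmap.mapping import predict_pixels, ramp_color, render_map, segment_foreground
from brixmap.pretreat import SNV, IdentityPretreatment


@pytest.fixture(scope="module")
def disc_scene():
    cfg = SynthConfig(seed=11)
    cube, rois, ref = generate_cube(
        cfg, n_discs=5, disc_radius_px=6, image_shape=(70, 90),
        pixel_noise_sd=0.002,
    )
    return cfg, cube, rois, ref


@pytest.fixture(scope="module")
def plsr_bundle(disc_scene):
    """Bundle trained on an independent synthetic spectra table (SNV+PLSR)."""
    cfg, cube, _, _ = disc_scene
    from brixmap import generate_spectra

    train = generate_spectra(SynthConfig(n_samples=200, seed=21)).to_table()
    pre = SNV().fit(train.x)
    xt = pre.transform(train.x)
    sub = SpectraTable(x=xt, wavelengths=train.wavelengths, y=train.y)
    model = fit_plsr(sub, n_components=3)
    return ModelBundle(
        pretreatment=pre,
        selected_bands=np.arange(train.n_bands),
        model=model,
        wavelengths=train.wavelengths,
    )


class TestPredictPixels:
    def test_disc_means_recover_ground_truth(self, disc_scene, plsr_bundle):
        cfg, cube, rois, ref = disc_scene
        mask = segment_foreground(cube, threshold_band=200, threshold=0.2)
        ssc_map = predict_pixels(cube, plsr_bundle, mask=mask)
        for (rid, *_), roi_mask in zip(rois.rois, rois.masks(70, 90)):
            truth = float(ref.set_index("sample_id").loc[rid, "ssc_brix"])
            per_disc = ssc_map.values[roi_mask]
            assert np.nanmean(per_disc) == pytest.approx(truth, abs=0.3)

    def test_uniform_cube_gives_uniform_map(self, plsr_bundle):
        from brixmap.cube_io import HyperCube
        from brixmap.synth import clean_spectrum

        cfg = SynthConfig(seed=0)
        spec = clean_spectrum(cfg, np.array([11.5]))[0]
        data = np.tile(spec, (20, 25, 1))
        cube = HyperCube(data=data, wavelengths=cfg.wavelengths, kind="reflectance")
        ssc_map = predict_pixels(cube, plsr_bundle)
        vals = ssc_map.masked_values()
        assert vals.max() - vals.min() < 1e-9

    def test_pixel_equal_to_roi_mean_predicts_identically(self, disc_scene, plsr_bundle):
        cfg, cube, rois, _ = disc_scene
        table = extract_mean_spectra(cube, rois)
        table_preds = plsr_bundle.predict_full(table.x)
        # a pixel whose spectrum equals the ROI mean gives the same number
        one = plsr_bundle.predict_full(table.x[2][None, :])
        assert one[0] == pytest.approx(table_preds[2], abs=1e-12)

    def test_wavelength_mismatch_raises(self, disc_scene, plsr_bundle):
        from brixmap.cube_io import HyperCube

        cfg, cube, _, _ = disc_scene
        shifted = HyperCube(
            data=cube.data, wavelengths=cube.wavelengths + 5.0, kind="reflectance"
        )
        with pytest.raises(MappingError, match="wavelength"):
            predict_pixels(shifted, plsr_bundle)

    def test_mean_of_pixel_predictions_commutes_for_linear_bundle(
        self, disc_scene, plsr_bundle
    ):
        # linear model + row-separable linear pretreatment: predicting the
        # mean spectrum equals averaging pixel-wise predictions... exactly
        # only for linear pretreatments; SNV is row-nonlinear, so compare a
        # no-pretreatment linear bundle instead
        cfg, cube, rois, _ = disc_scene
        from brixmap import generate_spectra

        train = generate_spectra(SynthConfig(n_samples=150, seed=31)).to_table()
        pre = IdentityPretreatment().fit(train.x)
        model = fit_plsr(train, n_components=3)
        bundle = ModelBundle(
            pretreatment=pre, selected_bands=np.arange(train.n_bands),
            model=model, wavelengths=train.wavelengths,
        )
        roi_mask = rois.masks(70, 90)[0]
        pixel_preds = bundle.predict_full(cube.data[roi_mask])
        mean_pred = bundle.predict_full(cube.data[roi_mask].mean(axis=0)[None, :])
        assert mean_pred[0] == pytest.approx(pixel_preds.mean(), abs=1e-9)


class TestSegmentation:
    def test_bimodal_scene_recovers_disc_masks_exactly(self):
        cfg = SynthConfig(seed=5)
        cube, rois, _ = generate_cube(
            cfg, n_discs=4, disc_radius_px=5, image_shape=(60, 70),
            background_reflectance=0.05, pixel_noise_sd=0.0,
        )
        band = int(np.argmin(np.abs(cfg.wavelengths - 900)))
        mask = segment_foreground(cube, band, 0.2)
        union = np.zeros((60, 70), bool)
        for m in rois.masks(60, 70):
            union |= m
        assert np.array_equal(mask, union)
        # geometry oracle: pixel count equals the discs' area total
        assert int(mask.sum()) == int(union.sum())

    def test_threshold_above_everything_raises(self):
        cfg = SynthConfig(seed=5)
        cube, _, _ = generate_cube(
            cfg, n_discs=2, disc_radius_px=5, image_shape=(40, 40)
        )
        with pytest.raises(SegmentationError):
            segment_foreground(cube, 100, 10.0)

    def test_keep_components_limits_blobs(self):
        cfg = SynthConfig(seed=6)
        cube, rois, _ = generate_cube(
            cfg, n_discs=4, disc_radius_px=4, image_shape=(60, 60)
        )
        band = 200
        mask = segment_foreground(cube, band, 0.2, keep_components=2)
        from scipy import ndimage

        _, n = ndimage.label(mask)
        assert n == 2


class TestRendering:
    def test_ramp_endpoints_and_midpoint(self):
        lo, hi = 8.0, 14.0
        from matplotlib import colormaps

        cmap = colormaps["jet"]
        assert ramp_color(lo, lo, hi) == cmap(0.0)
        assert ramp_color(hi, lo, hi) == cmap(1.0)
        assert ramp_color((lo + hi) / 2, lo, hi) == cmap(0.5)

    def test_rendering_does_not_alter_values(self, disc_scene, plsr_bundle, tmp_path):
        cfg, cube, _, _ = disc_scene
        mask = segment_foreground(cube, 200, 0.2)
        ssc_map = predict_pixels(cube, plsr_bundle, mask=mask)
        before = ssc_map.values.copy()
        render_map(ssc_map, cube=cube, path=tmp_path / "map.png")
        assert np.array_equal(
            np.nan_to_num(ssc_map.values), np.nan_to_num(before)
        )
        assert (tmp_path / "map.png").exists()

    def test_degenerate_render_range_rejected(self):
        with pytest.raises(RenderError):
            ramp_color(1.0, 5.0, 5.0)


class TestBundleSerialization:
    @pytest.mark.parametrize("kind", ["plsr", "svr", "mlr"])
    def test_json_round_trip_predicts_identically(self, kind, rng):
        from brixmap import fit_mlr

        x = 0.3 + 0.1 * rng.random((60, 12))
        y = 10 + 5 * x[:, 4] + 0.05 * rng.normal(size=60)
        wl = np.linspace(400, 1000, 12)
        t = SpectraTable(x=x, wavelengths=wl, y=y)
        pre = SNV().fit(t.x)
        xt = pre.transform(t.x)
        sel = np.array([2, 4, 7])
        sub = SpectraTable(x=xt[:, sel], wavelengths=wl[sel], y=y)
        if kind == "plsr":
            model = fit_plsr(sub, n_components=2)
        elif kind == "svr":
            model = fit_svr(sub, SVRParams(10.0, 0.1, 0.3))
        else:
            model = fit_mlr(sub)
        bundle = ModelBundle(
            pretreatment=pre, selected_bands=sel, model=model, wavelengths=wl
        )
        restored = ModelBundle.from_json(bundle.to_json())
        probe = 0.3 + 0.1 * rng.random((5, 12))
        assert np.allclose(
            bundle.predict_full(probe), restored.predict_full(probe), atol=1e-10
        )
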