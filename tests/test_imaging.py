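"""Image pipeline: calibration, masking, per-pixel estimation, phantoms."""
import numpy as np
import pytest

from mcti.bands import camera_band_system
from mcti.imaging import (MultispectralImage, PhantomRegion, PhantomSpec,
                          block_downsample, estimate_map, flatfield_correct,
                          read_stack, roi_mean_series, specular_mask,
                          synthesize_phantom, write_stack)
from mcti.inversion import RFHyperparams, TrainingSet, train_rf
from mcti.tissue_model import LayerProperties, TissueSample


@pytest.fixture(scope="module")
def bands():
    grid = np.arange(450.0, 721.0, 10.0)
    return camera_band_system(grid=grid)


def _sample(v_hb, s):
    return TissueSample((LayerProperties(v_hb, s, 18.9, 1.286, 0.88, 1.36,
                                         1800.0),))


@pytest.fixture(scope="module")
def phantom(bands, table):
    spec = PhantomSpec(shape=(24, 24), regions=[
        PhantomRegion((0, 24, 0, 12), _sample(0.08, 0.2)),
        PhantomRegion((0, 24, 12, 24), _sample(0.08, 0.8))],
        snr=50.0, specular_fraction=0.02, seed=5)
    return spec, synthesize_phantom(spec, bands, table)


@pytest.fixture(scope="module")
def trained_model(bands, table):
    """RF trained on single-layer spectra spanning the phantom's range."""
    from mcti.bands import band_integrate_array, normalize_features
    from mcti.transport import SimulationConfig, simulate_spectrum
    rng = np.random.default_rng(8)
    cfg = SimulationConfig(n_photons=3000, seed=21, weight_threshold=1e-2)
    rows, labels = [], []
    for i in range(120):
        v, s = rng.uniform(0.01, 0.1), rng.uniform(0.0, 1.0)
        sp = simulate_spectrum(_sample(v, s), bands.grid, table, cfg,
                               sample_index=i)
        rows.append(sp.r)
        labels.append((s, v))
    band_r = band_integrate_array(np.stack(rows), bands)
    X = normalize_features(band_r)
    model = train_rf(TrainingSet(X, np.array(labels)), RFHyperparams(seed=0),
                     band_fingerprint=bands.fingerprint())
    return model


class TestFlatfield:
    def _image(self, stack, dark, flat):
        return MultispectralImage(stack, dark, flat)

    def test_stack_equal_flatfield_gives_ones(self):
        flat = np.full((4, 4, 3), 900.0)
        dark = np.full((4, 4, 3), 100.0)
        out = flatfield_correct(self._image(flat.copy(), dark, flat))
        assert out == pytest.approx(np.ones_like(out))

    def test_stack_equal_dark_gives_zeros(self):
        flat = np.full((4, 4, 3), 900.0)
        dark = np.full((4, 4, 3), 100.0)
        out = flatfield_correct(self._image(dark.copy(), dark, flat))
        assert out == pytest.approx(np.zeros_like(out))

    def test_affine_embedding_inverted_exactly(self):
        rng = np.random.default_rng(0)
        dark = rng.uniform(80, 120, (5, 5, 4))
        flat = rng.uniform(800, 1200, (5, 5, 4))
        c = 0.37
        out = flatfield_correct(self._image(dark + c * (flat - dark),
                                            dark, flat))
        assert out == pytest.approx(np.full_like(out, c))

    def test_nonpositive_denominator_flagged_nan(self):
        dark = np.full((2, 2, 2), 100.0)
        flat = dark.copy()          # flat - dark == 0 everywhere
        out = flatfield_correct(self._image(dark + 1.0, dark, flat))
        assert np.isnan(out).all()


class TestSpecularMask:
    def test_threshold_one_masks_nothing(self):
        r = np.random.default_rng(1).uniform(0.1, 0.9, (8, 8, 3))
        assert not specular_mask(r, 1.0).any()

    def test_mask_monotone_in_threshold(self):
        r = np.random.default_rng(2).uniform(0.1, 1.0, (16, 16, 3))
        low = specular_mask(r, 0.6)
        high = specular_mask(r, 0.9)
        assert (low | high == low).all()   # high-threshold mask is a subset

    def test_injected_speculars_recalled(self, phantom):
        spec, (image, truth) = phantom
        refl = flatfield_correct(image)
        mask = specular_mask(refl)
        injected = ~truth.valid_mask & np.isfinite(truth.s_map + 0)
        injected = ~truth.valid_mask
        recall = mask[injected].mean()
        assert recall >= 0.95


class TestEstimateMap:
    def test_uniform_phantom_estimates_match_single_spectrum(
            self, bands, table, trained_model):
        spec = PhantomSpec(shape=(10, 10), regions=[
            PhantomRegion((0, 10, 0, 10), _sample(0.06, 0.5))],
            snr=np.inf, seed=6)
        image, truth = synthesize_phantom(spec, bands, table)
        refl = flatfield_correct(image)
        pm = estimate_map(refl, trained_model, bands,
                          specular_threshold=None)
        assert pm.valid_mask.all()
        assert np.ptp(pm.s_map) < 1e-12   # identical pixels, identical output

    def test_two_region_phantom_orders_oxygenation(self, phantom, bands,
                                                   trained_model):
        spec, (image, truth) = phantom
        refl = flatfield_correct(image)
        pm = estimate_map(refl, trained_model, bands)
        left = np.nanmedian(pm.s_map[:, :12])
        right = np.nanmedian(pm.s_map[:, 12:])
        assert left < right

    def test_chunked_processing_equals_unchunked(self, phantom, bands,
                                                 trained_model):
        spec, (image, truth) = phantom
        refl = flatfield_correct(image)
        a = estimate_map(refl, trained_model, bands, chunk_rows=37)
        b = estimate_map(refl, trained_model, bands)
        assert np.array_equal(a.s_map, b.s_map, equal_nan=True)

    def test_band_count_mismatch_rejected(self, bands, trained_model):
        with pytest.raises(ValueError):
            estimate_map(np.zeros((4, 4, 3)), trained_model, bands)


class TestRoiSeries:
    def test_constant_sequence_is_flat(self, phantom, bands, trained_model):
        spec, (image, truth) = phantom
        refl = flatfield_correct(image)
        pm = estimate_map(refl, trained_model, bands)
        series = roi_mean_series([pm, pm, pm], np.ones((24, 24), bool))
        assert series["mean_s"].nunique() == 1

    def test_programmed_step_drop_detected(self, bands, table,
                                           trained_model):
        frames = []
        for s in (0.8, 0.8, 0.2):
            spec = PhantomSpec(shape=(8, 8), regions=[
                PhantomRegion((0, 8, 0, 8), _sample(0.06, s))],
                snr=50.0, seed=30)
            image, _ = synthesize_phantom(spec, bands, table)
            pm = estimate_map(flatfield_correct(image), trained_model, bands,
                              specular_threshold=None)
            frames.append(pm)
        series = roi_mean_series(frames, np.ones((8, 8), bool))
        assert series["mean_s"][1] - series["mean_s"][2] > 0.2

    def test_empty_roi_yields_missing_not_zero(self, phantom, bands,
                                               trained_model):
        spec, (image, truth) = phantom
        pm = estimate_map(flatfield_correct(image), trained_model, bands)
        series = roi_mean_series([pm], np.zeros((24, 24), bool))
        assert np.isnan(series["mean_s"][0])
        assert series["n_valid"][0] == 0


class TestPhantom:
    def test_deterministic_given_seed(self, bands, table):
        spec = PhantomSpec(shape=(6, 6), regions=[
            PhantomRegion((0, 6, 0, 6), _sample(0.05, 0.4))],
            snr=20.0, seed=9)
        a, _ = synthesize_phantom(spec, bands, table)
        b, _ = synthesize_phantom(spec, bands, table)
        assert np.array_equal(a.stack, b.stack)

    def test_flatfield_inverts_noiseless_embedding(self, bands, table):
        spec = PhantomSpec(shape=(6, 6), regions=[
            PhantomRegion((0, 6, 0, 6), _sample(0.05, 0.4))],
            snr=np.inf, seed=10)
        image, _ = synthesize_phantom(spec, bands, table)
        refl = flatfield_correct(image)
        assert np.ptp(refl.reshape(-1, bands.n_bands), axis=0) == \
            pytest.approx(np.zeros(bands.n_bands), abs=1e-12)

    def test_region_outside_image_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(shape=(4, 4), regions=[
                PhantomRegion((0, 8, 0, 4), _sample(0.05, 0.4))])


class TestStackIO:
    def test_tiff_roundtrip(self, tmp_path, phantom):
        spec, (image, truth) = phantom
        p = tmp_path / "stack.tif"
        write_stack(p, image.stack, metadata={"bands": "spectrocam8"})
        again = read_stack(p)
        assert again.shape == image.stack.shape
        assert again == pytest.approx(image.stack, rel=1e-6)
        assert (tmp_path / "stack.tif.yaml").exists()

    def test_downsample_block_mean(self):
        x = np.arange(16, dtype=float).reshape(4, 4, 1)
        out = block_downsample(x, 2)
        assert out.shape == (2, 2, 1)
        assert out[0, 0, 0] == pytest.approx((0 + 1 + 4 + 5) / 4)
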