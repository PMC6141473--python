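"""Generator: SOC field statistics, forward model, features, bulk cutting."""

import numpy as np
import pytest

import corespec as cs
from corespec.synthetic import (
    Biopore,
    SyntheticCoreConfig,
    reflectance_model,
)
from corespec.preprocessing import (
    LOWER_MASK_BAND_NM,
    UPPER_MASK_BAND_NM,
)

from conftest import preprocess_core


@pytest.fixture(scope="module")
def plain_config():
    return SyntheticCoreConfig(seed=7)  # no biopores


class TestSOCField:
    def test_plough_horizon_moments(self, plain_config):
        """Empirical plough-horizon mean within 2% of 9 mg/g, CV within 15%
        of 0.2 at the default grid size."""
        fld, boundary, _ = cs.generate_soc_field(plain_config)
        depth = (np.arange(fld.shape[0]) + 0.5) * plain_config.pixel_size_cm
        plough = fld[depth < boundary]
        assert plough.mean() == pytest.approx(9.0, rel=0.02)
        cv = plough.std() / plough.mean()
        assert cv == pytest.approx(0.2, rel=0.15)

    def test_zero_variance_limit_gives_exact_profile(self):
        cfg = SyntheticCoreConfig(plough_cv=0.0, subsoil_cv_at_bottom=0.0, seed=3)
        fld, _, _ = cs.generate_soc_field(cfg)
        depth = (np.arange(fld.shape[0]) + 0.5) * cfg.pixel_size_cm
        expected = cfg.depth_profile_mean(depth)[:, None]
        np.testing.assert_allclose(fld, np.broadcast_to(expected, fld.shape))

    def test_noise_free_profile_non_increasing_below_plough(self):
        cfg = SyntheticCoreConfig(plough_cv=0.0, subsoil_cv_at_bottom=0.0, seed=0)
        fld, boundary, _ = cs.generate_soc_field(cfg)
        depth = (np.arange(fld.shape[0]) + 0.5) * cfg.pixel_size_cm
        profile = fld.mean(axis=1)[depth >= boundary]
        assert np.all(np.diff(profile) <= 1e-12)

    def test_field_strictly_positive_and_deterministic(self, plain_config):
        f1, _, _ = cs.generate_soc_field(plain_config)
        f2, _, _ = cs.generate_soc_field(plain_config)
        assert np.all(f1 > 0)
        np.testing.assert_array_equal(f1, f2)

    def test_biopore_soc_is_enrichment_times_matrix(self):
        """A factor-4 biopore over a ~4 mg/g matrix averages ~16 mg/g."""
        bp = Biopore(69.0, 83.0, 3.0, 5.0, 4.0)
        cfg = SyntheticCoreConfig(biopores=(bp,), seed=5)
        fld, _, truths = cs.generate_soc_field(cfg)
        (bt,) = truths
        assert bt.matrix_mean_soc == pytest.approx(4.0, abs=0.6)
        plateau_mean = fld[bt.plateau].mean()
        assert plateau_mean == pytest.approx(4.0 * bt.matrix_mean_soc, rel=0.02)

    def test_biopore_enrichment_vs_adjacent_matrix_within_10pct(self):
        """mean(biopore)/mean(matrix within 1 cm) ~ configured enrichment."""
        for bp_set in cs.synthetic.DEFAULT_BIOPORES[:2]:
            cfg = SyntheticCoreConfig(biopores=bp_set, seed=11)
            fld, _, truths = cs.generate_soc_field(cfg)
            for bt in truths:
                rr, cc = np.nonzero(bt.footprint)
                r0, r1 = rr.min(), rr.max()
                c0, c1 = cc.min(), cc.max()
                pad = int(round(1.0 / cfg.pixel_size_cm))  # 1 cm
                box = np.zeros_like(bt.footprint)
                box[max(r0 - pad, 0) : r1 + pad + 1,
                    max(c0 - pad, 0) : c1 + pad + 1] = True
                matrix = box & ~bt.footprint
                ratio = fld[bt.plateau].mean() / fld[matrix].mean()
                assert ratio == pytest.approx(bt.biopore.enrichment, rel=0.10)

    def test_out_of_extent_and_overlapping_biopores_rejected(self):
        with pytest.raises(ValueError, match="outside the core"):
            cs.generate_soc_field(
                SyntheticCoreConfig(biopores=(Biopore(90, 110, 3, 5, 2),))
            )
        with pytest.raises(ValueError, match="outside the core"):
            cs.generate_soc_field(
                SyntheticCoreConfig(biopores=(Biopore(50, 60, 0.1, 5, 2),))
            )
        with pytest.raises(ValueError, match="overlaps"):
            cs.generate_soc_field(
                SyntheticCoreConfig(
                    biopores=(Biopore(50, 60, 3, 5, 2), Biopore(55, 65, 3.1, 5, 3))
                )
            )


class TestForwardModel:
    def test_noise_free_round_trip_recovers_reflectance(self):
        """With scatter, illumination and noise off, normalisation against
        the target recovers the analytic reflectance exactly."""
        cfg = SyntheticCoreConfig(
            scatter_gain_sd=0.0,
            scatter_offset_sd=0.0,
            illumination_gradient_amplitude=0.0,
            band_noise_sd=0.0,
            seed=2,
        )
        fld, _, _ = cs.generate_soc_field(cfg)
        cube, target = cs.render_cube(fld, cfg)
        refl = cs.normalize_to_target(cube, target)
        expected = reflectance_model(fld, cfg.wavelengths())
        np.testing.assert_allclose(refl.values, expected, atol=1e-10)

    def test_illumination_gradient_cancels_in_normalization(self):
        cfg = SyntheticCoreConfig(
            scatter_gain_sd=0.0,
            scatter_offset_sd=0.0,
            illumination_gradient_amplitude=0.3,
            band_noise_sd=0.0,
            plough_cv=0.0,
            subsoil_cv_at_bottom=0.0,
            seed=2,
        )
        fld, _, _ = cs.generate_soc_field(cfg)
        cube, target = cs.render_cube(fld, cfg)
        # raw intensity differs across columns of a constant-SOC row ...
        row = cube.values[5]
        assert row[:, 0].max() / row[:, 0].min() > 1.1
        # ... but normalised reflectance does not
        refl = cs.normalize_to_target(cube, target)
        np.testing.assert_allclose(
            refl.values[5],
            np.broadcast_to(refl.values[5, 0], refl.values[5].shape),
            atol=1e-10,
        )

    def test_snv_removes_multiplicative_gain(self):
        """Two pixels of equal SOC but different gains have identical SNV
        spectra when the additive offset is zero."""
        wl = np.linspace(400, 990, 50)
        r = reflectance_model(np.array([5.0]), wl)[0]
        vals = np.stack([0.8 * r, 1.2 * r])[None, :, :]  # (1, 2, bands)
        cube = cs.SpectralCube(
            values=vals,
            wavelengths=wl,
            pixel_size_um=2000.0,
            treatment=cs.NORMALIZED_REFLECTANCE,
        )
        snv = cs.snv_transform(cube)
        np.testing.assert_allclose(snv.values[0, 0], snv.values[0, 1], atol=1e-12)

    def test_higher_soc_is_darker_at_every_band(self):
        wl = np.linspace(400, 990, 186)
        r_rich = reflectance_model(np.array([16.0]), wl)[0]
        r_poor = reflectance_model(np.array([2.0]), wl)[0]
        assert np.all(r_rich < r_poor)

    def test_rejects_nonpositive_field(self):
        cfg = SyntheticCoreConfig()
        with pytest.raises(ValueError, match="positive"):
            cs.render_cube(np.zeros((5, 3)), cfg)


class TestNonSoilFeatures:
    def test_zero_fraction_no_margin_is_all_soil(self):
        cfg = SyntheticCoreConfig(
            crack_fraction=0.0, background_margin_px=0, seed=4
        )
        fld, _, _ = cs.generate_soc_field(cfg)
        cube, _ = cs.render_cube(fld, cfg)
        _, truth = cs.plant_non_soil_features(cube, cfg)
        assert not truth.any()

    def test_planted_features_are_spectrally_distinguishable(self):
        core = cs.generate_core(SyntheticCoreConfig(seed=9))
        refl = cs.normalize_to_target(core.raw_cube, core.target)
        b980 = refl.band_index(UPPER_MASK_BAND_NM)
        b420 = refl.band_index(LOWER_MASK_BAND_NM)
        soil = ~core.non_soil_mask_truth
        soil_980 = refl.values[:, :, b980][soil]
        # crack pixels: darker at ~980 nm than any soil pixel
        cracks = core.non_soil_mask_truth.copy()
        cracks[:, : core.config.background_margin_px] = False
        cracks[:, -core.config.background_margin_px :] = False
        if cracks.any():
            assert refl.values[:, :, b980][cracks].max() < soil_980.min()
        # background columns: 980/420 ratio outside the soil range
        ratio = refl.values[:, :, b980] / refl.values[:, :, b420]
        bg = core.non_soil_mask_truth & ~cracks
        assert np.all(ratio[bg] < ratio[soil].min())

    def test_excessive_feature_fraction_rejected(self):
        cfg = SyntheticCoreConfig(crack_fraction=0.6)
        fld, _, _ = cs.generate_soc_field(cfg)
        cube, _ = cs.render_cube(fld, cfg)
        with pytest.raises(ValueError, match="50%"):
            cs.plant_non_soil_features(cube, cfg)


class TestBulkSamples:
    def test_default_study_set_yields_33_bulk_samples(self):
        cores = cs.default_core_set(seed=0, pixel_size_um=5000.0)
        counts = [len(c.bulk_truth) for c in cores]
        assert counts == [7, 7, 7, 6, 6]
        assert sum(counts) == 33

    def test_noise_free_constant_field_gives_exact_means(self):
        cfg = SyntheticCoreConfig(soc_measurement_sd=0.0, seed=0)
        fld = np.full(cfg.grid_shape(), 5.0)
        scheme = cs.default_cutting_schemes()["six"]
        for b in cs.cut_bulk_samples(fld, scheme, cfg):
            assert b.soc_mg_g == pytest.approx(5.0, abs=1e-12)

    def test_bulk_values_track_slab_truth_with_measurement_noise(self):
        cfg = SyntheticCoreConfig(seed=21)
        fld, _, _ = cs.generate_soc_field(cfg)
        scheme = cs.default_cutting_schemes()["seven"]
        resid = []
        for rep in range(30):
            rng = np.random.default_rng(rep)
            for b in cs.cut_bulk_samples(fld, scheme, cfg, rng=rng):
                depth = (np.arange(fld.shape[0]) + 0.5) * cfg.pixel_size_cm
                sel = (depth >= b.depth_top_cm) & (depth < b.depth_bottom_cm)
                resid.append(b.soc_mg_g - fld[sel].mean())
        resid = np.array(resid)
        assert abs(resid.mean()) < 0.1
        assert np.std(resid) == pytest.approx(cfg.soc_measurement_sd, rel=0.2)

    def test_gap_and_overlap_schemes_rejected(self):
        cfg = SyntheticCoreConfig(seed=0)
        fld, _, _ = cs.generate_soc_field(cfg)
        with pytest.raises(ValueError, match="gap or overlap"):
            cs.cut_bulk_samples(fld, [(0, 30), (40, 100)], cfg)
        with pytest.raises(ValueError, match="gap or overlap"):
            cs.cut_bulk_samples(fld, [(0, 30), (20, 100)], cfg)


def test_fixed_seed_reproduces_identical_core():
    cfg = SyntheticCoreConfig(seed=13)
    a = cs.generate_core(cfg)
    b = cs.generate_core(cfg)
    np.testing.assert_array_equal(a.soc_field, b.soc_field)
    np.testing.assert_array_equal(a.raw_cube.values, b.raw_cube.values)
    np.testing.assert_array_equal(a.non_soil_mask_truth, b.non_soil_mask_truth)


def test_mask_recovery_against_truth_is_better_than_99pct():
    core = cs.generate_core(SyntheticCoreConfig(seed=17))
    nr, _ = preprocess_core(core)
    agreement = np.mean(~nr.mask == core.non_soil_mask_truth)
    assert agreement >= 0.99
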