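"""Synthetic-image generator: molecule fields, rendering, moment oracles,
punctae and calibration series."""

import numpy as np
import pytest

import fifspec as fs
from fifspec.simulate import CALIBRATION_DENSITY_FLOOR


class TestMoleculeField:
    def test_zero_density_gives_empty_field(self):
        mix = fs.SpeciesMixture([(1, 0.0), (2, 0.0)])
        field = fs.simulate_molecule_field(mix, 10.0, 10.0, seed=1)
        assert field.shape == (0, 3)

    def test_poisson_count_within_tail_bound(self):
        # C=50/µm² over 100 µm² → mean 5000, SD √5000 ≈ 70.7; 4-SD bound
        mix = fs.SpeciesMixture.pure(1, 50.0)
        field = fs.simulate_molecule_field(mix, 10.0, 10.0, seed=7)
        assert abs(len(field) - 5000) < 4 * np.sqrt(5000)

    def test_protomer_bookkeeping_identity(self):
        mix = fs.SpeciesMixture([(1, 25.0), (2, 12.5)])
        field = fs.simulate_molecule_field(mix, 8.0, 8.0, seed=3)
        n_mono = int(np.sum(field[:, 2] == 1))
        n_di = int(np.sum(field[:, 2] == 2))
        assert np.sum(field[:, 2]) == n_mono + 2 * n_di

    def test_positions_inside_field(self):
        field = fs.simulate_molecule_field(fs.SpeciesMixture.pure(1, 30.0), 5.0, 3.0, seed=9)
        assert field[:, 0].min() >= 0 and field[:, 0].max() <= 5.0
        assert field[:, 1].min() >= 0 and field[:, 1].max() <= 3.0

    def test_non_positive_area_rejected(self):
        with pytest.raises(ValueError, match="area"):
            fs.simulate_molecule_field(fs.SpeciesMixture.pure(1, 1.0), -1.0, 5.0, seed=0)


class TestRenderImage:
    def test_empty_field_noise_free_is_constant_offset(self, psf):
        det = fs.DetectorModel(offset=100.0, read_noise_sd=0.0, background_mean=0.0, background_sd=0.0)
        img = fs.render_image(np.empty((0, 3)), psf, det, 0.06, (32, 32), seed=0)
        assert np.all(img.data == 100)

    def test_single_centered_monomer_peak(self, psf, quiet_detector):
        # molecule placed exactly at the centre of pixel (10, 10)
        x = y = (10 + 0.5) * 0.06
        field = np.array([[x, y, 1.0]])
        img = fs.render_image(field, psf, quiet_detector, 0.06, (21, 21), seed=0, q0=205.0)
        assert img.data[10, 10] == 100 + 205
        assert img.data.max() == img.data[10, 10]

    def test_peak_amplitude_scales_with_oligomer_size(self, psf, quiet_detector):
        x = y = (10 + 0.5) * 0.06
        for m in (1, 2, 4):
            field = np.array([[x, y, float(m)]])
            img = fs.render_image(field, psf, quiet_detector, 0.06, (21, 21), seed=0, q0=205.0)
            assert img.data[10, 10] == 100 + m * 205

    def test_fixed_seed_bit_identical(self, psf, detector):
        mix = fs.SpeciesMixture.pure(1, 30.0)
        img1, _ = fs.simulate_image(mix, psf, detector, (64, 64), 0.06, seed=11)
        img2, _ = fs.simulate_image(mix, psf, detector, (64, 64), 0.06, seed=11)
        assert np.array_equal(img1.data, img2.data)

    def test_negative_detector_parameters_rejected(self):
        with pytest.raises(ValueError):
            fs.DetectorModel(read_noise_sd=-1.0)

    def test_manifest_bookkeeping(self, psf, detector):
        mix = fs.SpeciesMixture([(1, 20.0), (2, 10.0)])
        _, manifest = fs.simulate_image(mix, psf, detector, (64, 64), 0.06, seed=5)
        assert manifest.total_protomers == manifest.molecule_counts[1] + 2 * manifest.molecule_counts[2]


class TestClosedFormMoments:
    def test_empty_mixture_gives_noise_only(self, psf):
        det = fs.DetectorModel(offset=50.0, read_noise_sd=3.0, background_mean=20.0, background_sd=4.0)
        mix = fs.SpeciesMixture([(1, 0.0)])
        mean, var = fs.closed_form_moments(mix, psf, det)
        assert mean == pytest.approx(70.0)
        assert var == pytest.approx(25.0)

    def test_monomer_brightness_identity(self, psf, detector):
        # (var − noise)/(mean − baseline) = γ·q0 exactly under the model
        mix = fs.SpeciesMixture.pure(1, 40.0)
        mean, var = fs.closed_form_moments(mix, psf, detector)
        ratio = (var - detector.noise_variance) / (mean - detector.baseline)
        assert ratio == pytest.approx(0.5 * mix.q0, rel=1e-12)

    def test_dimers_double_excess_variance_at_equal_protomer_density(self, psf, detector):
        mono = fs.SpeciesMixture.pure(1, 40.0)
        di = fs.SpeciesMixture.pure(2, 40.0)
        m1, v1 = fs.closed_form_moments(mono, psf, detector)
        m2, v2 = fs.closed_form_moments(di, psf, detector)
        assert m2 == pytest.approx(m1)
        assert (v2 - detector.noise_variance) == pytest.approx(2 * (v1 - detector.noise_variance))

    def test_rendered_image_matches_oracle(self, psf, detector):
        # quick single-mixture check; the full multi-mixture 3-SE sweep runs
        # in the acceptance suite
        mix = fs.SpeciesMixture([(1, 20.0), (2, 10.0)])
        mean_th, var_th = fs.closed_form_moments(mix, psf, detector)
        means, var_about = [], []
        for s in range(6):
            img, _ = fs.simulate_image(mix, psf, detector, (150, 150), 0.06, seed=100 + s)
            d = img.data.astype(float)
            means.append(d.mean())
            var_about.append(np.mean((d - mean_th) ** 2))
        se_mean = np.std(means, ddof=1) / np.sqrt(len(means))
        se_var = np.std(var_about, ddof=1) / np.sqrt(len(var_about))
        assert abs(np.mean(means) - mean_th) < 3 * se_mean + 0.5  # 0.5 a.u. quantisation guard
        assert abs(np.mean(var_about) - var_th) < 3 * se_var + 1.0


class TestPunctae:
    def test_zero_density_leaves_image_unchanged(self, monomer_image):
        img, _ = monomer_image
        out, mask = fs.add_punctae(img, fs.PunctaSpec(count_density=0.0), seed=1)
        assert np.array_equal(out.data, img.data)
        assert not mask.any()

    def test_zero_intensity_scale_leaves_image_unchanged(self, monomer_image):
        img, _ = monomer_image
        out, mask = fs.add_punctae(img, fs.PunctaSpec(count_density=0.1, intensity_scale=0.0), seed=2)
        assert np.array_equal(out.data, img.data)

    def test_masked_pixels_brighter_than_unmasked(self, monomer_image):
        img, _ = monomer_image
        out, mask = fs.add_punctae(img, fs.PunctaSpec(), seed=3)
        assert mask.any()
        assert out.data[mask].mean() > out.data[~mask].mean()


class TestCalibrationSeries:
    def test_series_structure_and_floor_flag(self, psf, detector):
        series = fs.simulate_calibration_series(
            [12.5, 20.0, 50.0, 100.0], 205.0, psf, detector, seeds=[1, 2, 3, 4], shape_px=(64, 64)
        )
        assert len(series) == 4
        for _, manifest in series:
            assert [m for m, _ in manifest.mixture.species] == [1]
        flagged = [m.flags for _, m in series]
        assert "below_calibration_floor" in flagged[0]
        assert all("below_calibration_floor" not in f for f in flagged[1:])
        assert 12.5 < CALIBRATION_DENSITY_FLOOR

    def test_non_positive_density_rejected(self, psf, detector):
        with pytest.raises(ValueError):
            fs.simulate_calibration_series([0.0], 205.0, psf, detector, seeds=[1])


class TestPatchSeries:
    def test_realised_fractions_close_to_target(self, psf, detector):
        target = {1: 0.25, 2: 0.5, 4: 0.25}
        patches, realised = fs.simulate_patch_series(
            target, 8, (28, 52), psf, detector, seed=5, patch_shape_px=(40, 40)
        )
        assert len(patches) == 8
        assert sum(realised.values()) == pytest.approx(1.0)
        for m, f in target.items():
            assert realised[m] == pytest.approx(f, abs=0.15)

    def test_each_patch_is_single_species(self, psf, detector):
        patches, _ = fs.simulate_patch_series(
            {1: 0.5, 2: 0.5}, 4, (30, 50), psf, detector, seed=6, patch_shape_px=(40, 40)
        )
        for _, manifest in patches:
            assert len(manifest.mixture.species) == 1
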