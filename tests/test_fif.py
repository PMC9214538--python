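"""FIF spectrometry: segmentation, brightness estimation, spectrograms,
oligomer-fraction decomposition, despotting and condition comparison."""

import numpy as np
import pandas as pd
import pytest

import fifspec as fs
from fifspec.fif import (
    ConcentrationBin,
    BrightnessSpectrogram,
    OligomerFractions,
    SegmentExcluded,
)
from fifspec.psf_correlation import rect_mean_correlation, variance_deflation
from conftest import rect_roi


def flat_image(value=500, shape=(100, 100)):
    return fs.ConfocalImage(np.full(shape, value, dtype=np.uint16), 0.06)


class TestSegmentation:
    def test_square_roi_tiles_into_expected_segments(self):
        img = flat_image(shape=(80, 80))
        segs = fs.segment_rois(img, [rect_roi(60)])
        assert len(segs) == 9
        assert all(s.area_px == 400 for s in segs)

    def test_roi_smaller_than_segment_warns_and_yields_nothing(self):
        img = flat_image(shape=(40, 40))
        with pytest.warns(UserWarning, match="too small"):
            segs = fs.segment_rois(img, [rect_roi(19)])
        assert segs == []

    def test_segments_carry_raw_pixels(self):
        img = flat_image(value=777, shape=(40, 40))
        segs = fs.segment_rois(img, [rect_roi(20)])
        assert len(segs) == 1
        assert np.all(segs[0].pixels == 777)

    def test_exclude_mask_drops_overlapping_segments(self):
        img = flat_image(shape=(40, 40))
        mask = np.zeros((40, 40), dtype=bool)
        mask[5, 5] = True  # inside the first 20x20 tile
        segs = fs.segment_rois(img, [rect_roi(40)], exclude_mask=mask)
        assert len(segs) == 3

    def test_triangle_roi_only_interior_tiles(self):
        img = flat_image(shape=(100, 100))
        tri = np.array([(0.0, 0.0), (100.0, 0.0), (0.0, 100.0)])
        segs = fs.segment_rois(img, [tri])
        assert 0 < len(segs) < 25  # strictly fewer than the bounding box tiling


class TestSegmentHistogramFit:
    def test_recovers_known_gaussian(self):
        rng = np.random.default_rng(4)
        pixels = rng.normal(500.0, 50.0, size=(20, 20))
        mean, sd, ok = fs.fit_segment_histogram(pixels)
        assert ok
        assert mean == pytest.approx(500.0, rel=0.02)
        assert sd == pytest.approx(50.0, rel=0.10)

    def test_constant_segment_not_ok(self):
        mean, sd, ok = fs.fit_segment_histogram(np.full((20, 20), 300.0))
        assert not ok
        assert sd == 0.0

    def test_fit_tracks_sample_moments_on_unimodal_data(self):
        rng = np.random.default_rng(5)
        hits = 0
        n_trials = 200
        for _ in range(n_trials):
            x = rng.normal(800.0, 60.0, size=(20, 20))
            mean, sd, ok = fs.fit_segment_histogram(x)
            if ok and abs(mean - x.mean()) < 0.05 * x.mean() and abs(sd - x.std(ddof=1)) < 0.2 * x.std(ddof=1):
                hits += 1
        assert hits >= 0.95 * n_trials


class TestEffectiveBrightness:
    def test_algebraic_identity(self, detector):
        # hand-computed: var 10000+noise, corrected mean 400, γ=0.5 → ε=50
        sd = np.sqrt(10000.0 + detector.noise_variance)
        eps = fs.effective_brightness(detector.baseline + 400.0, sd, detector, gamma=0.5)
        assert eps == pytest.approx(10000.0 / (0.5 * 400.0))

    def test_deflation_rescales_variance(self, detector):
        sd = np.sqrt(10000.0 + detector.noise_variance)
        eps_raw = fs.effective_brightness(detector.baseline + 400.0, sd, detector, 0.5, deflation=1.0)
        eps_cor = fs.effective_brightness(detector.baseline + 400.0, sd, detector, 0.5, deflation=0.8)
        assert eps_cor == pytest.approx(eps_raw / 0.8)

    def test_noise_only_segment_excluded(self, detector):
        with pytest.raises(SegmentExcluded):
            fs.effective_brightness(detector.baseline - 1.0, 30.0, detector)
        with pytest.raises(SegmentExcluded):
            fs.effective_brightness(detector.baseline + 100.0, 0.5 * detector.read_noise_sd, detector)

    def test_monomer_segments_center_on_q0(self, monomer_segments):
        ok = monomer_segments[~monomer_segments["excluded"]]
        assert ok["eps_eff"].mean() == pytest.approx(205.0, rel=0.10)

    def test_dimer_segments_center_on_2q0(self, dimer_segments):
        ok = dimer_segments[~dimer_segments["excluded"]]
        assert ok["eps_eff"].mean() == pytest.approx(410.0, rel=0.10)

    def test_variance_deflation_magnitude(self, psf):
        # 20×20 segments at 60-nm pixels lose ~12% of the signal variance
        d = variance_deflation((20, 20), psf.w_xy, 0.06)
        assert 0.85 < d < 0.91
        # large regions lose almost nothing
        assert variance_deflation((400, 400), psf.w_xy, 0.06) > 0.99

    def test_mask_and_rect_correlation_agree_on_rectangles(self, psf):
        mask = np.zeros((60, 60), dtype=bool)
        mask[10:40, 15:45] = True
        from fifspec.psf_correlation import mask_mean_correlation

        rho_mask = mask_mean_correlation(mask, psf.w_xy, 0.06)
        rho_rect = rect_mean_correlation((30, 30), psf.w_xy, 0.06)
        assert rho_mask == pytest.approx(rho_rect, rel=1e-3)


class TestSegmentConcentration:
    def test_zero_signal_gives_zero(self, detector):
        assert fs.segment_concentration(detector.baseline, detector, w_xy_um=0.2656) == 0.0

    def test_known_density_recovered(self, monomer_segments):
        ok = monomer_segments[~monomer_segments["excluded"]]
        assert ok["concentration"].mean() == pytest.approx(40.0, rel=0.10)

    def test_composition_invariance(self, monomer_segments, dimer_segments):
        # same protomer density simulated as monomers vs dimers
        c1 = monomer_segments[~monomer_segments["excluded"]]["concentration"].mean()
        c2 = dimer_segments[~dimer_segments["excluded"]]["concentration"].mean()
        assert abs(c2 - c1) / c1 < 0.05


class TestDespot:
    def test_contaminated_image_mask_quality(self, monomer_image):
        img, _ = monomer_image
        contaminated, true_mask = fs.add_punctae(img, fs.PunctaSpec(), seed=77)
        _, spot = fs.despot(contaminated)
        recall = (spot & true_mask).sum() / true_mask.sum()
        false_pos = (spot & ~true_mask).sum() / (~true_mask).sum()
        assert recall >= 0.80
        assert false_pos <= 0.05

    def test_clean_image_barely_masked(self, monomer_image):
        img, _ = monomer_image
        _, spot = fs.despot(img)
        assert spot.mean() < 0.01

    def test_brightness_recovery_after_despot(self, monomer_image, psf, detector):
        img, _ = monomer_image
        contaminated, _ = fs.add_punctae(img, fs.PunctaSpec(count_density=0.08), seed=78)
        _, spot = fs.despot(contaminated)
        roi = [rect_roi(240)]
        eps_clean = fs.analyze_segments(fs.segment_rois(img, roi), detector, psf, 0.06)
        eps_desp = fs.analyze_segments(
            fs.segment_rois(contaminated, roi, exclude_mask=spot), detector, psf, 0.06
        )
        m_clean = eps_clean[~eps_clean["excluded"]]["eps_eff"].mean()
        m_desp = eps_desp[~eps_desp["excluded"]]["eps_eff"].mean()
        assert abs(m_desp - m_clean) / m_clean < 0.15


def _stats_frame(concentrations, eps=None, replicate="rep_0"):
    concentrations = np.asarray(concentrations, dtype=float)
    if eps is None:
        eps = np.full_like(concentrations, 205.0)
    return pd.DataFrame(
        {
            "concentration": concentrations,
            "eps_eff": eps,
            "excluded": False,
            "replicate": replicate,
        }
    )


class TestSpectrogram:
    def test_single_density_populates_one_bin(self):
        spect = fs.build_spectrogram(_stats_frame(np.full(100, 30.0)))
        assert [b.n for b in spect.bins] == [0, 100, 0, 0, 0]

    def test_edge_value_goes_to_upper_bin(self):
        spect = fs.build_spectrogram(_stats_frame([25.0]))
        assert spect.bins[1].n == 1
        assert spect.bins[0].n == 0

    def test_below_floor_and_above_range_excluded(self):
        spect = fs.build_spectrogram(_stats_frame([5.0, 14.9, 30.0, 65.0, 120.0]))
        assert spect.n_segments == 1
        assert spect.n_excluded_below_floor == 2
        assert spect.n_excluded_above_range == 2

    def test_low_n_flag(self):
        spect = fs.build_spectrogram(_stats_frame(np.full(10, 30.0)))
        assert spect.bins[1].low_n

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            spect = fs.build_spectrogram(_stats_frame([5.0]))
        assert spect.n_segments == 0

    def test_every_value_lands_in_exactly_one_bin(self):
        rng = np.random.default_rng(6)
        conc = rng.uniform(0, 80, 500)
        spect = fs.build_spectrogram(_stats_frame(conc))
        total = spect.n_segments + spect.n_excluded_below_floor + spect.n_excluded_above_range
        assert total == 500


def _synthetic_spectrogram(weights, n=600, sd_frac=0.35, seed=0, e1=205.0):
    """Spectrogram with one 25–35 bin of ε values drawn from a mixture of
    per-size normals (size n gets weight weights[n-1])."""
    rng = np.random.default_rng(seed)
    sizes = rng.choice(np.arange(1, len(weights) + 1), size=n, p=np.asarray(weights) / np.sum(weights))
    eps = rng.normal(sizes * e1, sd_frac * sizes * e1)
    eps = np.clip(eps, 1.0, None)
    b = ConcentrationBin(25.0, 35.0, eps, np.repeat("rep_0", n))
    return BrightnessSpectrogram(bin_edges=(25.0, 35.0), bins=[b])


class TestOligomerFractions:
    def test_pure_monomer_distribution_recovered(self):
        rng = np.random.default_rng(8)
        eps = rng.normal(205.0, 30.0, 500)
        b = ConcentrationBin(25.0, 35.0, eps, np.repeat("rep_0", 500))
        spect = BrightnessSpectrogram(bin_edges=(25.0, 35.0), bins=[b])
        of = fs.fit_oligomer_fractions(spect)
        row = of.table.iloc[0]
        assert row["fit_ok"]
        assert row["f_mono"] >= 0.95

    def test_even_monomer_dimer_mixture_recovered(self):
        spect = _synthetic_spectrogram([0.5, 0.5], seed=9)
        row = fs.fit_oligomer_fractions(spect).table.iloc[0]
        assert row["f_mono"] == pytest.approx(0.5, abs=0.1)
        assert row["f_di"] == pytest.approx(0.5, abs=0.1)

    def test_fractions_sum_to_one(self):
        for seed in range(3):
            spect = _synthetic_spectrogram([0.2, 0.4, 0.2, 0.2], seed=seed)
            row = fs.fit_oligomer_fractions(spect).table.iloc[0]
            if row["fit_ok"]:
                assert row["f_mono"] + row["f_di"] + row["f_oligo"] == pytest.approx(1.0, abs=1e-6)

    def test_low_n_bin_skipped(self):
        b = ConcentrationBin(25.0, 35.0, np.full(5, 205.0), np.repeat("rep_0", 5))
        of = fs.fit_oligomer_fractions(BrightnessSpectrogram((25.0, 35.0), [b]))
        assert of.table.iloc[0]["flag"] == "low_n"
        assert not of.table.iloc[0]["fit_ok"]

    def test_protomer_weighting_shifts_mass_to_larger_sizes(self):
        spect = _synthetic_spectrogram([0.5, 0.5], seed=10)
        f_seg = fs.fit_oligomer_fractions(spect, weighting="segment").table.iloc[0]
        f_pro = fs.fit_oligomer_fractions(spect, weighting="protomer").table.iloc[0]
        assert f_pro["f_di"] > f_seg["f_di"]


class TestPooling:
    @staticmethod
    def _fractions_from_rows(rows):
        cols = ["bin_low", "bin_high", "n_segments", "f_mono", "f_di", "f_oligo",
                "sd_mono", "sd_di", "sd_oligo", "fit_ok", "flag"]
        t = pd.DataFrame(rows, columns=cols)
        return OligomerFractions(t, 205.0, 4, "segment", "linear")

    def test_single_bin_passthrough(self):
        of = self._fractions_from_rows(
            [[25.0, 35.0, 100, 0.2, 0.5, 0.3, 0.01, 0.01, 0.01, True, ""]]
        )
        pooled = fs.pool_fractions(of)
        assert (pooled["f_mono"], pooled["f_di"], pooled["f_oligo"]) == (0.2, 0.5, 0.3)

    def test_equal_weight_mean(self):
        of = self._fractions_from_rows(
            [
                [25.0, 35.0, 50, 0.2, 0.5, 0.3, 0.01, 0.01, 0.01, True, ""],
                [35.0, 45.0, 50, 0.4, 0.4, 0.2, 0.01, 0.01, 0.01, True, ""],
            ]
        )
        pooled = fs.pool_fractions(of)
        assert pooled["f_mono"] == pytest.approx(0.3)
        assert pooled["f_di"] == pytest.approx(0.45)
        assert pooled["f_oligo"] == pytest.approx(0.25)
        assert pooled["f_mono"] + pooled["f_di"] + pooled["f_oligo"] == pytest.approx(1.0)

    def test_out_of_range_bins_ignored_and_empty_range_fails(self):
        of = self._fractions_from_rows(
            [[15.0, 25.0, 50, 0.2, 0.5, 0.3, 0.01, 0.01, 0.01, True, ""]]
        )
        with pytest.raises(ValueError, match="no fitted bins"):
            fs.pool_fractions(of, 25.0, 55.0)


class TestCompareConditions:
    def test_identical_conditions_not_significant(self):
        reps = np.array([[0.2, 0.5, 0.3], [0.25, 0.45, 0.30], [0.22, 0.46, 0.32]])
        out = fs.compare_conditions({"a": reps, "b": reps.copy()})
        for cls in out["classes"].values():
            for pair in cls["tukey"].values():
                assert pair["p"] > 0.99

    def test_requires_two_conditions_and_two_replicates(self):
        reps = np.array([[0.2, 0.5, 0.3], [0.25, 0.45, 0.3]])
        with pytest.raises(ValueError, match="two conditions"):
            fs.compare_conditions({"a": reps})
        with pytest.raises(ValueError, match="replicates"):
            fs.compare_conditions({"a": reps, "b": reps[:1]})

    def test_monomer_shift_detected_at_reference_effect_size(self):
        # basal 0.147 vs treated 0.440 monomer, replicate SD 0.06, n=3
        rng = np.random.default_rng(12)
        basal = np.column_stack([rng.normal(0.147, 0.06, 3), rng.normal(0.40, 0.06, 3), rng.normal(0.45, 0.06, 3)])
        treated = np.column_stack([rng.normal(0.44, 0.06, 3), rng.normal(0.36, 0.06, 3), rng.normal(0.20, 0.06, 3)])
        out = fs.compare_conditions({"basal": basal, "treated": treated})
        assert out["classes"]["monomer"]["anova_p"] < 0.05

    def test_tukey_flags_only_the_outlier_condition(self):
        rng = np.random.default_rng(13)

        def cond(mu):
            m = rng.normal(mu, 0.05, 3)
            d = rng.normal(0.4, 0.05, 3)
            return np.column_stack([m, d, 1 - m - d])

        out = fs.compare_conditions({"a": cond(0.15), "b": cond(0.15), "c": cond(0.44)})
        tuk = out["classes"]["monomer"]["tukey"]
        assert tuk["a vs b"]["p"] >= 0.05
        assert tuk["a vs c"]["p"] < 0.05
        assert tuk["b vs c"]["p"] < 0.05
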