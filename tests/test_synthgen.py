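"""Generator ground truth, determinism, and statistical structure."""

import numpy as np
import pytest
from scipy import stats as sps

from cermap import (
    BlotTruth,
    CellGeometry,
    LocalizationProfile,
    NoiseModel,
    calibrate_chrom_enrich,
    chromosome_fraction,
    correct_contamination,
    expected_image,
    generate_blot,
    generate_cell_image,
    generate_cohort,
)
from cermap.quantify import mean_intensity
from cermap.synthgen import GeometryError, SaturationError

from oracles import pixel_sum_cer_oracle


class TestTrueCER:
    def test_flat_uniform_cell_has_cer_exactly_one(self, uniform_profile, noiseless):
        geom = CellGeometry(thickness_power=0.0)
        cell = generate_cell_image(uniform_profile, geom, noiseless, seed=1)
        assert cell.true_cer == 1.0

    def test_dome_thickness_inflates_uniform_cer_above_one(self, uniform_profile, noiseless, geometry):
        # a uniform fluorophore reads >1 because the plate sits in the
        # thickest part of the cell
        cell = generate_cell_image(uniform_profile, geometry, noiseless, seed=1)
        assert cell.true_cer > 1.0

    def test_flat_cell_enrichment_matches_pixel_sum_oracle(self, noiseless):
        geom = CellGeometry(thickness_power=0.0, soft_sigma=0.0)
        prof = LocalizationProfile(name="x3", chrom_enrich=3.0)
        cell = generate_cell_image(prof, geom, noiseless, seed=2)
        oracle = pixel_sum_cer_oracle(
            cell.fluor_image, cell.chrom_mask_truth, cell.cell_mask_truth,
            geom.background_level,
        )
        assert cell.true_cer == pytest.approx(oracle, abs=1e-12)
        # the denominator is the whole-cell mean, which itself contains the
        # enriched plate, so the CER sits below the raw 3x enrichment
        plate_frac = cell.chrom_mask_truth.sum() / cell.cell_mask_truth.sum()
        assert cell.true_cer == pytest.approx(3.0 / (1.0 + 2.0 * plate_frac), rel=1e-12)

    def test_noise_free_image_equals_expected_image_everywhere(self, uniform_profile, geometry, noiseless):
        cell = generate_cell_image(uniform_profile, geometry, noiseless, seed=3)
        expected = expected_image(uniform_profile, geometry)
        assert np.max(np.abs(cell.fluor_image - expected)) == 0.0

    def test_true_cer_monotone_in_compartment_enrichment(self, small_geometry, noiseless):
        chrom_grid = [0.5, 1.0, 1.5, 2.0, 3.0]
        cers = [
            generate_cell_image(
                LocalizationProfile(name="g", chrom_enrich=e), small_geometry, noiseless, seed=0
            ).true_cer
            for e in chrom_grid
        ]
        assert all(b > a for a, b in zip(cers, cers[1:]))
        spindle_grid = [1.0, 1.5, 2.0, 3.0]
        cers_s = [
            generate_cell_image(
                LocalizationProfile(name="g", chrom_enrich=2.0, spindle_enrich=s),
                small_geometry, noiseless, seed=0,
            ).true_cer
            for s in spindle_grid
        ]
        assert all(b < a for a, b in zip(cers_s, cers_s[1:]))


class TestMasksAndGeometry:
    def test_masks_are_mutually_consistent(self, uniform_profile, geometry, noiseless):
        cell = generate_cell_image(uniform_profile, geometry, noiseless, seed=4)
        assert (cell.chrom_mask_truth & ~cell.cell_mask_truth).sum() == 0  # plate ⊂ cell
        assert (cell.background_mask & cell.cell_mask_truth).sum() == 0  # bg ∩ cell = ∅

    def test_plate_outside_cell_is_a_geometry_error(self):
        with pytest.raises(GeometryError):
            CellGeometry(cell_axes=(20.0, 20.0), plate_axes=(25.0, 8.0))

    def test_missing_background_margin_is_a_geometry_error(self):
        with pytest.raises(GeometryError):
            CellGeometry(image_shape=(100, 100), cell_axes=(48.0, 60.0))

    def test_saturating_expression_refused_unless_clipped(self, geometry, noiseless):
        prof = LocalizationProfile(name="hot", expression_mean=5000.0)
        with pytest.raises(SaturationError):
            generate_cell_image(prof, geometry, noiseless, seed=5)
        cell = generate_cell_image(prof, geometry, noiseless, seed=5, clip=True)
        assert cell.saturated
        assert cell.fluor_image.max() <= geometry.bit_depth

    def test_hand_roi_stays_within_two_px_of_truth_plate(self, uniform_profile, geometry, default_noise):
        from scipy import ndimage

        cell = generate_cell_image(uniform_profile, geometry, default_noise, seed=6)
        dist_out = ndimage.distance_transform_edt(~cell.chrom_mask_truth)
        dist_in = ndimage.distance_transform_edt(cell.chrom_mask_truth)
        added = cell.chrom_roi & ~cell.chrom_mask_truth
        removed = ~cell.chrom_roi & cell.chrom_mask_truth
        assert dist_out[added].max(initial=0) <= 2.0 + 1e-9
        assert dist_in[removed].max(initial=0) <= 2.0 + 1e-9


class TestCohort:
    def test_same_seed_gives_bitwise_identical_cohort(self, uniform_profile, small_geometry, default_noise):
        a = generate_cohort(uniform_profile, 8, small_geometry, default_noise, seed=11)
        b = generate_cohort(uniform_profile, 8, small_geometry, default_noise, seed=11)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.fluor_image, cb.fluor_image)
            assert np.array_equal(ca.chrom_roi, cb.chrom_roi)
            assert ca.expression == cb.expression
            assert ca.plate_defined == cb.plate_defined

    def test_different_seeds_differ(self, uniform_profile, small_geometry, default_noise):
        a = generate_cohort(uniform_profile, 2, small_geometry, default_noise, seed=11)
        b = generate_cohort(uniform_profile, 2, small_geometry, default_noise, seed=12)
        assert not np.array_equal(a[0].fluor_image, b[0].fluor_image)

    def test_zero_expression_cv_and_no_noise_gives_identical_true_cer(self, small_geometry, noiseless):
        prof = LocalizationProfile(name="fixed", chrom_enrich=2.0, expression_cv=0.0,
                                   plate_undefined_prob=0.0)
        cells = generate_cohort(prof, 6, small_geometry, noiseless, seed=13)
        cers = {c.true_cer for c in cells}
        assert len(cers) == 1

    def test_cohort_size_must_be_positive(self, uniform_profile, small_geometry, noiseless):
        with pytest.raises(ValueError):
            generate_cohort(uniform_profile, 0, small_geometry, noiseless, seed=0)

    def test_expression_window_exceedance_matches_lognormal_oracle(self, geometry, noiseless):
        """Fraction of cells with whole-cell mean outside [50, 500] agrees
        with the closed-form lognormal tail probability."""
        prof = LocalizationProfile(name="cv05", expression_cv=0.5, plate_undefined_prob=0.0)
        # analytic map expression -> whole-cell mean is affine: bg + E * k
        k = (
            mean_intensity(expected_image(prof, geometry, expression=1.0), geometry.masks()["cell"])
            - geometry.background_level
        )
        sigma = np.sqrt(np.log1p(prof.expression_cv**2))
        scale = prof.expression_mean * np.exp(-(sigma**2) / 2)
        dist = sps.lognorm(s=sigma, scale=scale)
        lo, hi = (50.0 - geometry.background_level) / k, (500.0 - geometry.background_level) / k
        p_out = dist.cdf(lo) + dist.sf(hi)

        outside = total = 0
        for seed in (0, 1, 2):
            for cell in generate_cohort(prof, 50, geometry, noiseless, seed=seed):
                cm = mean_intensity(cell.fluor_image, cell.cell_mask_truth)
                outside += not (50.0 <= cm <= 500.0)
                total += 1
        se = np.sqrt(p_out * (1 - p_out) / total)
        assert abs(outside / total - p_out) <= 3 * se + 1e-12


class TestCalibration:
    @pytest.mark.parametrize("target", [1.0, 1.37, 1.87, 2.45])
    def test_calibrated_profile_hits_target_true_cer(self, target, geometry, noiseless):
        e = calibrate_chrom_enrich(target, geometry)
        prof = LocalizationProfile(name="cal", chrom_enrich=e)
        cell = generate_cell_image(prof, geometry, noiseless, seed=7)
        assert cell.true_cer == pytest.approx(target, abs=1e-9)

    def test_unreachable_target_raises(self, geometry):
        with pytest.raises(ValueError):
            calibrate_chrom_enrich(1e6, geometry)


class TestBlots:
    def test_even_split_without_contamination(self):
        s = generate_blot(BlotTruth(true_fraction=0.5, contamination=0.0, total_signal=100.0))
        assert s.chr_band == pytest.approx(50.0)
        assert s.cyto_band == pytest.approx(50.0)

    def test_pure_cytoplasmic_marker_reads_contamination_level(self):
        # tubulin-like: no true association, 17% pelleting carry-over
        s = generate_blot(BlotTruth(true_fraction=0.0, contamination=0.17))
        assert chromosome_fraction(s) == pytest.approx(17.0)

    def test_blot_roundtrip_recovers_true_fraction(self):
        s = generate_blot(BlotTruth(true_fraction=0.4, contamination=0.1))
        corr = correct_contamination(chromosome_fraction(s), 10.0)
        assert corr.proportional == pytest.approx(40.0, abs=1e-12)

    def test_noisy_blot_is_reproducible_and_positive(self):
        t = BlotTruth(true_fraction=0.3, contamination=0.17, noise_cv=0.1)
        a, b = generate_blot(t, seed=5), generate_blot(t, seed=5)
        assert (a.wce, a.chr_band, a.cyto_band) == (b.wce, b.chr_band, b.cyto_band)
        assert min(a.wce, a.chr_band, a.cyto_band) > 0


class TestBinning:
    def test_2x2_binning_halves_frame_and_preserves_cer(self, uniform_profile, geometry):
        noise = NoiseModel(photon_scale=None, read_sd=0.0, bin2x2=True)
        cell = generate_cell_image(
            LocalizationProfile(name="b", chrom_enrich=2.0), geometry, noise, seed=8
        )
        assert cell.fluor_image.shape == (80, 80)
        assert cell.chrom_mask_truth.shape == (80, 80)
        chrom = mean_intensity(cell.fluor_image, cell.chrom_mask_truth)
        whole = mean_intensity(cell.fluor_image, cell.cell_mask_truth)
        bg = geometry.background_level
        assert (chrom - bg) / (whole - bg) == pytest.approx(cell.true_cer, rel=0.02)
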