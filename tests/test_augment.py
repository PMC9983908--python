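"""Augmentation operators: conservation, identity, moment scaling,
unbiasedness and lineage."""

import numpy as np
import pytest

from relaxcell import (
    AugmentationParams,
    BoundaryError,
    augment_dataset,
    augment_spectrum,
    detect_peaks,
    shift_peak,
    stretch_peak,
)
from relaxcell.augment import CELL_LINE_PRESET, MSC_PRESET


class TestShiftPeak:
    def test_zero_shift_is_identity(self, cell_media_spectrum):
        peak = detect_peaks(cell_media_spectrum)[0]
        out = shift_peak(cell_media_spectrum, peak, 0.0, 0.0)
        np.testing.assert_allclose(out.intensity, cell_media_spectrum.intensity, atol=1e-9)

    def test_centroid_moves_by_shift(self, make_blob_spectrum):
        spec = make_blob_spectrum([(0.5, 0.05, 1.0)], width=0.25)
        peak = detect_peaks(spec)[0]
        out = shift_peak(spec, peak, 0.1, 0.0)
        moved = detect_peaks(out)[0]
        half_cell = 0.5 * (np.exp(np.log(spec.t1_grid[1] / spec.t1_grid[0])) - 1) * 0.6
        assert moved.centroid_t1 - peak.centroid_t1 == pytest.approx(0.1, abs=half_cell)
        assert moved.centroid_t2 == pytest.approx(peak.centroid_t2, rel=0.05)

    def test_total_intensity_conserved(self, cell_media_spectrum):
        peak = detect_peaks(cell_media_spectrum)[0]
        out = shift_peak(cell_media_spectrum, peak, 0.05, 0.005)
        assert out.total_intensity == pytest.approx(
            cell_media_spectrum.total_intensity, rel=1e-6
        )

    def test_off_peak_intensity_untouched(self, cell_media_spectrum):
        peaks = detect_peaks(cell_media_spectrum)
        cell = peaks[0]
        media = peaks[1]
        out = shift_peak(cell_media_spectrum, cell, 0.05, 0.005)
        np.testing.assert_array_equal(
            out.intensity[media.mask], cell_media_spectrum.intensity[media.mask]
        )

    def test_off_grid_shift_raises_boundary_error(self, make_blob_spectrum):
        spec = make_blob_spectrum([(0.5, 0.05, 1.0)])
        peak = detect_peaks(spec)[0]
        with pytest.raises(BoundaryError):
            shift_peak(spec, peak, 100.0, 0.0)


class TestStretchPeak:
    def test_zero_stretch_is_identity(self, cell_media_spectrum):
        peak = detect_peaks(cell_media_spectrum)[0]
        out = stretch_peak(cell_media_spectrum, peak, 0.0, 0.0)
        np.testing.assert_allclose(out.intensity, cell_media_spectrum.intensity, atol=1e-9)

    @pytest.mark.parametrize("s", [0.1, -0.1])
    def test_second_moment_scales_quadratically(self, s):
        # oracle: resample the peak component on a dense uniform linear grid
        # and measure the variance there (node sums on the coarse log grid
        # are a biased moment estimator); a fine spectral grid keeps the
        # operator's own O(h^2) resampling blur below the tolerance
        from scipy.interpolate import RegularGridInterpolator

        from relaxcell import Spectrum2D
        from relaxcell.spectrum import log_grid

        t1g, t2g = log_grid(192, 1e-3, 15.0), log_grid(192, 1e-3, 5.0)
        x_, y_ = np.log(t1g)[:, None], np.log(t2g)[None, :]
        inten = np.exp(
            -((x_ - np.log(0.5)) ** 2 + (y_ - np.log(0.05)) ** 2) / (2 * 0.25**2)
        )
        spec = Spectrum2D(t1g, t2g, inten)
        peak = detect_peaks(spec)[0]
        out = stretch_peak(spec, peak, s, s)
        xs = np.linspace(0.1, 1.6, 1200)
        ys = np.linspace(0.004, 0.25, 800)
        xx, yy = np.meshgrid(xs, ys, indexing="ij")
        pts = np.stack([xx.ravel(), yy.ravel()], axis=1)

        def variances(intensity):
            interp = RegularGridInterpolator(
                (spec.t1_grid, spec.t2_grid), intensity, bounds_error=False, fill_value=0.0
            )
            f = interp(pts).reshape(xx.shape)
            tot = f.sum()
            mx = (f.sum(axis=1) @ xs) / tot
            my = (f.sum(axis=0) @ ys) / tot
            vx = (f.sum(axis=1) @ (xs - mx) ** 2) / tot
            vy = (f.sum(axis=0) @ (ys - my) ** 2) / tot
            return vx, vy

        masked = np.where(peak.mask, spec.intensity, 0.0)
        background = spec.intensity - masked  # sub-threshold tails, untouched
        v1_a, v2_a = variances(masked)
        v1_b, v2_b = variances(out.intensity - background)
        assert v1_b / v1_a == pytest.approx((1 + s) ** 2, rel=0.03)
        assert v2_b / v2_a == pytest.approx((1 + s) ** 2, rel=0.03)

    def test_total_intensity_conserved(self, cell_media_spectrum):
        peak = detect_peaks(cell_media_spectrum)[0]
        out = stretch_peak(cell_media_spectrum, peak, 0.08, -0.05)
        assert out.total_intensity == pytest.approx(
            cell_media_spectrum.total_intensity, rel=1e-6
        )

    def test_degenerate_scale_rejected(self, cell_media_spectrum):
        peak = detect_peaks(cell_media_spectrum)[0]
        with pytest.raises(ValueError):
            stretch_peak(cell_media_spectrum, peak, -1.0, 0.0)


class TestAugmentSpectrum:
    def test_factor_counts_with_original(self, cell_media_spectrum):
        out = augment_spectrum(cell_media_spectrum, AugmentationParams(factor=5, seed=1))
        assert len(out) == 6
        assert sum(s.is_original for s in out) == 1
        assert out[0].is_original

    def test_factor_zero_returns_only_original(self, cell_media_spectrum):
        out = augment_spectrum(cell_media_spectrum, AugmentationParams(factor=0, seed=1))
        assert len(out) == 1 and out[0].is_original

    def test_deterministic_given_seed(self, cell_media_spectrum):
        p = AugmentationParams(factor=3, seed=7)
        a = augment_spectrum(cell_media_spectrum, p)
        b = augment_spectrum(cell_media_spectrum, p)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.intensity, y.intensity)

    def test_every_variant_conserves_intensity(self, cell_media_spectrum):
        out = augment_spectrum(cell_media_spectrum, AugmentationParams(factor=5, seed=1))
        for s in out:
            assert s.total_intensity == pytest.approx(
                cell_media_spectrum.total_intensity, rel=1e-6
            )

    def test_no_peaks_raises(self, grids):
        from relaxcell import Spectrum2D

        t1g, t2g = grids
        empty = Spectrum2D(t1g, t2g, np.zeros((t1g.size, t2g.size)))
        with pytest.raises(ValueError):
            augment_spectrum(empty, AugmentationParams(factor=1))

    def test_growing_shift_merges_class_clouds(self, make_blob_spectrum):
        # larger shift std blurs class structure: the ratio of between-class
        # centroid distance to within-class spread decreases
        from relaxcell import centroid_table

        def cloud_stats(shift_std):
            recs = {"A": [], "B": []}
            for label, (c1, c2) in {"A": (0.45, 0.04), "B": (0.6, 0.055)}.items():
                spec = make_blob_spectrum([(c1, c2, 1.0)], width=0.15, sample_id=label, class_label=label)
                params = AugmentationParams(
                    shift_std_t1=shift_std, shift_std_t2=shift_std, stretch_std=0.0,
                    factor=25, seed=3, keep_original=False,
                )
                for rec in centroid_table(augment_spectrum(spec, params)):
                    recs[rec.class_label].append([rec.t1, rec.t2])
            a, b = np.array(recs["A"]), np.array(recs["B"])
            between = np.linalg.norm(a.mean(0) - b.mean(0))
            within = 0.5 * (a.std(0).mean() + b.std(0).mean())
            return between / within

        assert cloud_stats(0.001) > cloud_stats(0.05)


class TestAugmentDataset:
    def test_output_count_and_presets(self, make_blob_spectrum):
        spectra = [
            make_blob_spectrum([(0.5, 0.05, 1.0)], sample_id=f"s{i}", class_label="A")
            for i in range(3)
        ]
        out, lineage = augment_dataset(spectra, AugmentationParams(factor=5, seed=0))
        assert len(out) == 3 * 6
        assert lineage.shape[0] == 18
        assert MSC_PRESET.shift_std_t1 == 0.005 and MSC_PRESET.stretch_std == 0.01
        assert CELL_LINE_PRESET.shift_std_t1 == 0.001 and CELL_LINE_PRESET.stretch_std == 0.01

    def test_lineage_parents_exist_and_shift_matches_displacement(self, make_blob_spectrum):
        spectra = [
            make_blob_spectrum([(0.5, 0.05, 1.0)], width=0.22, sample_id=f"s{i}", class_label="A")
            for i in range(2)
        ]
        params = AugmentationParams(
            shift_std_t1=0.02, shift_std_t2=0.002, stretch_std=0.0, factor=4, seed=9
        )
        out, lineage = augment_dataset(spectra, params)
        by_id = {s.sample_id: s for s in out}
        parents = {s.sample_id for s in spectra}
        assert set(lineage.parent_id) <= parents
        cell_t1 = np.log(spectra[0].t1_grid[1] / spectra[0].t1_grid[0])
        for row in lineage.itertuples(index=False):
            assert row.parent_id in by_id or row.parent_id in parents
            if row.is_original:
                continue
            child = by_id[row.sample_id]
            parent = next(s for s in spectra if s.sample_id == row.parent_id)
            c_child = detect_peaks(child)[0]
            c_parent = detect_peaks(parent)[0]
            achieved = c_child.centroid_t1 - c_parent.centroid_t1
            # recorded shift equals achieved centroid displacement within
            # one (local) grid cell
            cell_width = c_parent.centroid_t1 * cell_t1
            assert abs(achieved - row.applied_dt1) <= cell_width

    def test_unbiased_draw_distribution(self, make_blob_spectrum):
        spec = make_blob_spectrum([(0.5, 0.05, 1.0)], width=0.2, sample_id="s")
        params = AugmentationParams(
            shift_std_t1=0.01, shift_std_t2=0.01, stretch_std=0.01, factor=400,
            seed=21, keep_original=False,
        )
        log: list = []
        augment_spectrum(spec, params, applied_log=log)
        dt1 = np.array([d["dt1"] for d in log])
        n = dt1.size
        assert n >= 390  # redraws are rare at this std
        assert abs(dt1.mean()) <= 3 * 0.01 / np.sqrt(n)
        assert dt1.std() == pytest.approx(0.01, rel=0.1)
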