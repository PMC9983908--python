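"""Peak detection, tagging, weighted centroids and the cell-peak crop."""

import numpy as np
import pytest

from relaxcell import (
    Spectrum2D,
    centroid_table,
    crop_to_cell_window,
    detect_peaks,
    tag_peaks,
    weighted_centroid,
)
from relaxcell.features import CELL_WINDOW_T1_MAX, CELL_WINDOW_T2_MAX


class TestDetectPeaks:
    def test_zero_spectrum_gives_no_peaks(self, grids):
        t1g, t2g = grids
        spec = Spectrum2D(t1g, t2g, np.zeros((t1g.size, t2g.size)))
        assert detect_peaks(spec) == []

    def test_cell_plus_media_gives_two_peaks(self, cell_media_spectrum):
        assert len(detect_peaks(cell_media_spectrum)) == 2

    def test_differentiated_msc_gives_three_peaks(self, make_blob_spectrum):
        spec = make_blob_spectrum(
            [(0.7, 0.08, 0.7), (0.28, 0.19, 0.5), (2.5, 1.5, 0.5)], width=0.12
        )
        assert len(detect_peaks(spec)) == 3

    def test_sorted_by_total_intensity(self, cell_media_spectrum):
        peaks = detect_peaks(cell_media_spectrum)
        assert peaks[0].total_intensity >= peaks[1].total_intensity

    def test_threshold_monotonicity(self, make_blob_spectrum):
        spec = make_blob_spectrum([(0.5, 0.05, 1.0), (2.5, 1.5, 0.2), (0.3, 0.2, 0.08)])
        counts = [
            len(detect_peaks(spec, threshold_frac=f)) for f in (0.02, 0.05, 0.1, 0.3, 0.6, 0.9)
        ]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_min_area_filter(self, grids):
        t1g, t2g = grids
        inten = np.zeros((t1g.size, t2g.size))
        inten[10, 10] = 1.0  # single-cell speck
        inten[30:34, 30:34] = 0.8
        spec = Spectrum2D(t1g, t2g, inten)
        peaks = detect_peaks(spec, min_area=4, min_intensity_frac=0.0)
        assert len(peaks) == 1
        assert peaks[0].area == 16

    def test_invalid_threshold(self, cell_media_spectrum):
        with pytest.raises(ValueError):
            detect_peaks(cell_media_spectrum, threshold_frac=1.5)


class TestTagPeaks:
    def test_media_window_tagging(self, cell_media_spectrum):
        peaks = tag_peaks(detect_peaks(cell_media_spectrum))
        tags = {p.tag for p in peaks}
        assert tags == {"cell", "media"}
        media = next(p for p in peaks if p.tag == "media")
        assert media.centroid_t1 >= 2.0

    def test_single_long_t1_region_is_media(self, make_blob_spectrum):
        spec = make_blob_spectrum([(2.5, 1.5, 1.0)])
        peaks = tag_peaks(detect_peaks(spec))
        assert [p.tag for p in peaks] == ["media"]

    def test_single_short_region_is_cell(self, make_blob_spectrum):
        spec = make_blob_spectrum([(0.6, 0.08, 1.0)])
        peaks = tag_peaks(detect_peaks(spec))
        assert [p.tag for p in peaks] == ["cell"]

    def test_second_cell_window_peak_tagged_lipid(self, make_blob_spectrum):
        spec = make_blob_spectrum(
            [(0.7, 0.08, 0.7), (0.28, 0.19, 0.5), (2.5, 1.5, 0.5)], width=0.12
        )
        peaks = tag_peaks(detect_peaks(spec))
        by_tag = {p.tag: p for p in peaks}
        assert set(by_tag) == {"cell", "lipid", "media"}
        assert by_tag["lipid"].centroid_t1 < by_tag["cell"].centroid_t1

    def test_empty_list_passthrough(self):
        assert tag_peaks([]) == []


class TestWeightedCentroid:
    def test_single_cell_mask(self, grids):
        t1g, t2g = grids
        inten = np.zeros((t1g.size, t2g.size))
        i, j = 20, 30
        inten[i, j] = 2.0
        spec = Spectrum2D(t1g, t2g, inten)
        mask = inten > 0
        assert weighted_centroid(mask, spec) == (pytest.approx(t1g[i]), pytest.approx(t2g[j]))

    def test_two_equal_cells_average(self, grids):
        t1g, t2g = grids
        inten = np.zeros((t1g.size, t2g.size))
        inten[20, 30] = 1.0
        inten[22, 30] = 1.0
        spec = Spectrum2D(t1g, t2g, inten)
        c1, c2 = weighted_centroid(inten > 0, spec)
        assert c1 == pytest.approx(0.5 * (t1g[20] + t1g[22]))
        assert c2 == pytest.approx(t2g[30])

    def test_blob_centroid_matches_brute_force(self, make_blob_spectrum):
        spec = make_blob_spectrum([(0.5, 0.05, 1.0)])
        peak = detect_peaks(spec)[0]
        # independent brute-force summation over the mask
        num1 = num2 = den = 0.0
        for i in range(spec.shape[0]):
            for j in range(spec.shape[1]):
                if peak.mask[i, j]:
                    w = spec.intensity[i, j]
                    num1 += w * spec.t1_grid[i]
                    num2 += w * spec.t2_grid[j]
                    den += w
        c1, c2 = weighted_centroid(peak, spec)
        assert c1 == pytest.approx(num1 / den, rel=1e-12)
        assert c2 == pytest.approx(num2 / den, rel=1e-12)

    def test_scaling_invariance(self, cell_media_spectrum):
        peak = detect_peaks(cell_media_spectrum)[0]
        scaled = cell_media_spectrum.copy_with(intensity=5.0 * cell_media_spectrum.intensity)
        assert weighted_centroid(peak.mask, scaled) == weighted_centroid(
            peak.mask, cell_media_spectrum
        )

    def test_zero_intensity_region_rejected(self, grids):
        t1g, t2g = grids
        spec = Spectrum2D(t1g, t2g, np.zeros((t1g.size, t2g.size)))
        mask = np.zeros(spec.shape, dtype=bool)
        mask[3, 3] = True
        with pytest.raises(ValueError):
            weighted_centroid(mask, spec)


class TestCropToCellWindow:
    def test_default_window_bounds(self, cell_media_spectrum):
        cropped = crop_to_cell_window(cell_media_spectrum)
        assert cropped.t1_grid[-1] <= CELL_WINDOW_T1_MAX == 3.0079
        assert cropped.t2_grid[-1] <= CELL_WINDOW_T2_MAX == 0.4062

    def test_media_peak_excluded(self, cell_media_spectrum):
        cropped = crop_to_cell_window(cell_media_spectrum)
        peaks = tag_peaks(detect_peaks(cropped))
        assert len(peaks) == 1
        assert peaks[0].tag == "cell"

    def test_idempotent(self, cell_media_spectrum):
        once = crop_to_cell_window(cell_media_spectrum)
        twice = crop_to_cell_window(once)
        np.testing.assert_array_equal(once.intensity, twice.intensity)
        np.testing.assert_array_equal(once.t1_grid, twice.t1_grid)

    def test_window_covering_grid_is_identity(self, cell_media_spectrum):
        out = crop_to_cell_window(cell_media_spectrum, t1_max=1e9, t2_max=1e9)
        np.testing.assert_array_equal(out.intensity, cell_media_spectrum.intensity)

    def test_empty_overlap_rejected(self, cell_media_spectrum):
        with pytest.raises(ValueError):
            cell_media_spectrum.crop(t1_max=1e-9, t2_max=1e-9)


class TestCentroidTable:
    def test_one_record_per_sample_with_cell_peak(self, make_blob_spectrum):
        spectra = [
            make_blob_spectrum([(0.5, 0.05, 1.0), (2.5, 1.5, 0.5)], sample_id=f"s{i}", class_label="A")
            for i in range(3)
        ]
        records = centroid_table(spectra)
        assert [r.sample_id for r in records] == ["s0", "s1", "s2"]
        assert all(r.class_label == "A" for r in records)

    def test_media_only_sample_excluded_not_raised(self, make_blob_spectrum):
        spectra = [
            make_blob_spectrum([(0.5, 0.05, 1.0), (2.5, 1.5, 0.5)], sample_id="cells"),
            make_blob_spectrum([(2.5, 1.5, 1.0)], sample_id="media_only"),
        ]
        excl = []
        records = centroid_table(spectra, exclusions=excl)
        assert [r.sample_id for r in records] == ["cells"]
        assert excl == ["media_only"]

    def test_stronger_of_two_cell_peaks_selected(self, make_blob_spectrum):
        spec = make_blob_spectrum(
            [(0.7, 0.08, 0.7), (0.28, 0.19, 0.5), (2.5, 1.5, 0.5)], width=0.12, sample_id="msc"
        )
        (rec,) = centroid_table([spec])
        # the lipid peak (0.28 s) is weaker; record must track the water cell peak
        assert rec.t1 == pytest.approx(0.7, rel=0.1)

    def test_empty_cohort(self):
        assert centroid_table([]) == []

    def test_phenotype_clusters_separate(self, make_blob_spectrum):
        # round-trip property: between-class distance exceeds within-class
        # spread for well-separated phenotypes
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(0)
        spectra = []
        for label, (c1, c2) in {"A": (0.4, 0.04), "B": (1.2, 0.2)}.items():
            for i in range(6):
                j1 = c1 * 10 ** rng.normal(0, 0.03)
                j2 = c2 * 10 ** rng.normal(0, 0.03)
                spectra.append(
                    make_blob_spectrum(
                        [(j1, j2, 1.0), (2.5, 1.5, 0.5)], sample_id=f"{label}{i}", class_label=label
                    )
                )
        records = centroid_table(spectra)
        x = np.log10([[r.t1, r.t2] for r in records])
        labels = [r.class_label for r in records]
        assert silhouette_score(x, labels) > 0
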