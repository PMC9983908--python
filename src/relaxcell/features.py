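"""Peak detection and weighted-centroid features of T1/T2 spectra.

A spectrum of a cell sample shows a short-relaxation "cell peak" and a
long-relaxation "media peak" (adipogenically differentiated MSCs add a
lipid peak).  Peaks are connected components above a fractional intensity
threshold; each peak is reduced to its intensity-weighted (T1, T2) centroid
— the feature pair fed to the SVM — and the CNN input is the spectrum
cropped to the cell-peak window T1 <= 3.0079 s, T2 <= 0.4062 s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label

from .spectrum import Spectrum2D

__all__ = [
    "PeakRegion",
    "CentroidRecord",
    "detect_peaks",
    "tag_peaks",
    "weighted_centroid",
    "crop_to_cell_window",
    "centroid_table",
    "CELL_WINDOW_T1_MAX",
    "CELL_WINDOW_T2_MAX",
    "MEDIA_T1_MIN",
]

logger = logging.getLogger(__name__)

#: Cell-peak crop window upper bounds (seconds).
CELL_WINDOW_T1_MAX = 3.0079
CELL_WINDOW_T2_MAX = 0.4062
#: Media peaks sit at T1 of roughly 2-3 s; anything at or above this T1 is
#: tagged as media.
MEDIA_T1_MIN = 2.0


@dataclass
class PeakRegion:
    """A connected peak of the spectrum.

    ``mask`` is a boolean array on the spectrum's grid; ``bbox`` holds
    ``(i0, i1, j0, j1)`` half-open index ranges.
    """

    mask: np.ndarray
    total_intensity: float
    bbox: Tuple[int, int, int, int]
    centroid_t1: float
    centroid_t2: float
    tag: str = "unassigned"

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class CentroidRecord:
    """Weighted-centroid feature of one sample's cell peak."""

    sample_id: str
    class_label: str
    t1: float
    t2: float

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("centroid coordinates must be positive")


def weighted_centroid(region_or_mask, spec: Spectrum2D) -> Tuple[float, float]:
    """Intensity-weighted mean (T1, T2) in linear seconds over a peak mask."""
    mask = region_or_mask.mask if isinstance(region_or_mask, PeakRegion) else region_or_mask
    w = spec.intensity * mask
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total intensity in region")
    t1 = float((w.sum(axis=1) @ spec.t1_grid) / total)
    t2 = float((w.sum(axis=0) @ spec.t2_grid) / total)
    return t1, t2


def detect_peaks(
    spec: Spectrum2D,
    threshold_frac: float = 0.05,
    min_area: int = 4,
    min_intensity_frac: float = 0.01,
) -> List[PeakRegion]:
    """Connected components of the super-threshold intensity map.

    Cells with intensity >= ``threshold_frac`` of the spectrum maximum are
    grouped with 8-connectivity; components smaller than ``min_area`` cells
    or carrying less than ``min_intensity_frac`` of the total intensity are
    discarded.  Peaks are returned sorted by total intensity, descending.
    """
    if not (0 < threshold_frac < 1):
        raise ValueError("threshold_frac must be in (0, 1)")
    peak = spec.intensity.max()
    if peak <= 0:
        return []
    above = spec.intensity >= threshold_frac * peak
    labels, n = cc_label(above, connectivity=2, return_num=True)
    total = spec.total_intensity
    regions: List[PeakRegion] = []
    for lab in range(1, n + 1):
        mask = labels == lab
        inten = float(spec.intensity[mask].sum())
        if mask.sum() < min_area or inten < min_intensity_frac * total:
            continue
        ii, jj = np.nonzero(mask)
        c1, c2 = weighted_centroid(mask, spec)
        regions.append(
            PeakRegion(
                mask=mask,
                total_intensity=inten,
                bbox=(int(ii.min()), int(ii.max()) + 1, int(jj.min()), int(jj.max()) + 1),
                centroid_t1=c1,
                centroid_t2=c2,
            )
        )
    regions.sort(key=lambda r: -r.total_intensity)
    return regions


def tag_peaks(regions: List[PeakRegion], media_t1_min: float = MEDIA_T1_MIN) -> List[PeakRegion]:
    """Assign cell / media / lipid tags by centroid position.

    Peaks with centroid T1 at or beyond ``media_t1_min`` are media; the rest
    are cell peaks, except that when two or more peaks fall in the cell
    window the shortest-T1 one among them is tagged lipid (the second cell
    peak of differentiated MSCs).
    """
    cell_regions = []
    for r in regions:
        r.tag = "media" if r.centroid_t1 >= media_t1_min else "cell"
        if r.tag == "cell":
            cell_regions.append(r)
    if len(cell_regions) >= 2:
        min(cell_regions, key=lambda r: r.centroid_t1).tag = "lipid"
    return regions


def crop_to_cell_window(
    spec: Spectrum2D,
    t1_max: float = CELL_WINDOW_T1_MAX,
    t2_max: float = CELL_WINDOW_T2_MAX,
) -> Spectrum2D:
    """Restrict the spectrum to the cell-peak window (excludes the media
    peak, whose T2 exceeds the window)."""
    return spec.crop(t1_max=t1_max, t2_max=t2_max)


def cell_peak(spec: Spectrum2D, include_lipid: bool = False, **detect_kw) -> Optional[PeakRegion]:
    """Highest-intensity cell-tagged peak of a spectrum, or None."""
    regions = tag_peaks(detect_peaks(spec, **detect_kw))
    tags = ("cell", "lipid") if include_lipid else ("cell",)
    cells = [r for r in regions if r.tag in tags]
    return cells[0] if cells else None


def centroid_table(
    spectra: Iterable[Spectrum2D],
    exclusions: Optional[list] = None,
    **detect_kw,
) -> List[CentroidRecord]:
    """One centroid record per sample from its strongest cell peak.

    Samples with no cell-tagged peak (e.g. media-only controls) are logged
    and appended to ``exclusions`` when a list is given, never raised.
    """
    records: List[CentroidRecord] = []
    for spec in spectra:
        region = cell_peak(spec, **detect_kw)
        if region is None:
            logger.info("sample %s excluded: no cell peak detected", spec.sample_id)
            if exclusions is not None:
                exclusions.append(spec.sample_id)
            continue
        records.append(
            CentroidRecord(
                sample_id=spec.sample_id,
                class_label=spec.class_label,
                t1=region.centroid_t1,
                t2=region.centroid_t2,
            )
        )
    return records


def centroids_to_frame(records: Sequence[CentroidRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.sample_id, r.class_label, r.t1, r.t2) for r in records],
        columns=["sample_id", "class_label", "t1", "t2"],
    )
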