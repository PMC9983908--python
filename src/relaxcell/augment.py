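"""Peak-based augmentation of T1/T2 spectra.

The dataset multiplier for CNN training: every detected peak is, per
iteration, translated by a random shift (Gaussian, std in seconds) and
stretched about its centroid by a random percentage of its width (Gaussian
std, applied as a scale factor 1+s), both in linear time coordinates, with
the peak's total intensity held constant.  Run n times, the augmenter turns
each measured spectrum into n new spectra (plus the flagged original).

Shifts and stretches act on the spectrum seen as a function of linear
(T1, T2): values on the log-spaced grid are re-sampled by bilinear
interpolation at the inverse-transformed coordinates and the moved peak is
rescaled to its exact original mass, so conservation holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .features import PeakRegion, detect_peaks
from .spectrum import Spectrum2D

__all__ = [
    "AugmentationParams",
    "BoundaryError",
    "shift_peak",
    "stretch_peak",
    "augment_spectrum",
    "augment_dataset",
    "MSC_PRESET",
    "CELL_LINE_PRESET",
]


class BoundaryError(ValueError):
    """A shift or stretch pushed peak mass off the grid."""


@dataclass(frozen=True)
class AugmentationParams:
    """Random shift/stretch configuration.

    ``shift_std_t1`` / ``shift_std_t2`` are standard deviations in seconds;
    ``stretch_std`` is the std of the fractional width change (0.01 = 1%).
    ``factor`` is the number of augmented copies per input spectrum.
    """

    shift_std_t1: float = 0.005
    shift_std_t2: float = 0.005
    stretch_std: float = 0.01
    factor: int = 5
    seed: int = 0
    keep_original: bool = True

    def __post_init__(self) -> None:
        if self.shift_std_t1 < 0 or self.shift_std_t2 < 0 or self.stretch_std < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.factor < 0:
            raise ValueError("factor must be >= 0")


#: Final augmentation parameters for MSC CNN training: 1% stretch, 5 ms shift.
MSC_PRESET = AugmentationParams(shift_std_t1=0.005, shift_std_t2=0.005, stretch_std=0.01)
#: Final augmentation parameters for cell-line CNN training: 1% stretch, 1 ms shift.
CELL_LINE_PRESET = AugmentationParams(shift_std_t1=0.001, shift_std_t2=0.001, stretch_std=0.01)

_MASS_TOL = 1e-6  # max tolerated relative mass loss before a move counts as off-grid


def _move_peak(
    spec: Spectrum2D,
    region: PeakRegion,
    dt1: float,
    dt2: float,
    s1: float,
    s2: float,
) -> Spectrum2D:
    """Shared shift+stretch kernel: translate by (dt1, dt2) and scale about
    the centroid by (1+s1, 1+s2), conserving the peak's mass exactly."""
    if (1.0 + s1) <= 0 or (1.0 + s2) <= 0:
        raise ValueError("stretch factors must stay positive")
    peak = np.where(region.mask, spec.intensity, 0.0)
    mass = peak.sum()
    if mass <= 0:
        raise ValueError("region carries no intensity")
    c1, c2 = region.centroid_t1, region.centroid_t2
    # forward map x -> c + (1+s)(x - c) + d must keep the peak's bounding
    # box inside the grid
    i0, i1, j0, j1 = region.bbox
    lo1, hi1 = spec.t1_grid[i0], spec.t1_grid[i1 - 1]
    lo2, hi2 = spec.t2_grid[j0], spec.t2_grid[j1 - 1]
    new1 = c1 + (1.0 + s1) * (np.array([lo1, hi1]) - c1) + dt1
    new2 = c2 + (1.0 + s2) * (np.array([lo2, hi2]) - c2) + dt2
    if (
        new1[0] < spec.t1_grid[0]
        or new1[1] > spec.t1_grid[-1]
        or new2[0] < spec.t2_grid[0]
        or new2[1] > spec.t2_grid[-1]
    ):
        raise BoundaryError(
            f"move (dt1={dt1:g}, dt2={dt2:g}, s1={s1:g}, s2={s2:g}) pushes the peak off-grid"
        )
    interp = RegularGridInterpolator(
        (spec.t1_grid, spec.t2_grid), peak, bounds_error=False, fill_value=0.0
    )
    # sample the inverse map at every grid node
    tt1, tt2 = np.meshgrid(spec.t1_grid, spec.t2_grid, indexing="ij")
    src1 = c1 + (tt1 - dt1 - c1) / (1.0 + s1)
    src2 = c2 + (tt2 - dt2 - c2) / (1.0 + s2)
    moved = interp(np.stack([src1.ravel(), src2.ravel()], axis=1)).reshape(spec.shape)
    moved = np.clip(moved, 0.0, None)
    moved_mass = moved.sum()
    if moved_mass <= 0:
        raise BoundaryError("peak left the grid entirely")
    moved *= mass / moved_mass
    background = spec.intensity - peak
    return spec.copy_with(intensity=background + moved, is_original=False)


def shift_peak(spec: Spectrum2D, region: PeakRegion, dt1: float, dt2: float) -> Spectrum2D:
    """Translate one peak by (dt1, dt2) seconds in linear coordinates.

    Off-peak intensity is untouched; total intensity is conserved.  Raises
    :class:`BoundaryError` when the peak would leave the grid.
    """
    return _move_peak(spec, region, dt1, dt2, 0.0, 0.0)


def stretch_peak(spec: Spectrum2D, region: PeakRegion, s1: float, s2: float) -> Spectrum2D:
    """Rescale one peak about its centroid by factors (1+s1, 1+s2),
    renormalized to conserve the peak's total intensity."""
    return _move_peak(spec, region, 0.0, 0.0, s1, s2)


def augment_spectrum(
    spec: Spectrum2D,
    params: AugmentationParams,
    rng: Optional[np.random.Generator] = None,
    max_attempts: int = 100,
    detect_kw: Optional[dict] = None,
    applied_log: Optional[list] = None,
) -> List[Spectrum2D]:
    """Generate ``params.factor`` randomized variants of one spectrum.

    Each iteration draws a fresh shift ~ N(0, shift_std) and stretch
    ~ N(0, stretch_std) per detected peak; draws that push a peak off the
    grid are redrawn (up to ``max_attempts``) rather than clipped, to keep
    the applied-parameter distribution unbiased.  The unmodified original
    is prepended (flagged ``is_original``) when ``keep_original``.  When an
    ``applied_log`` list is passed, one dict per (variant, peak) records
    the draw that was actually applied.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    regions = detect_peaks(spec, **(detect_kw or {}))
    if not regions:
        raise ValueError(f"no peaks detected in {spec.sample_id!r}; nothing to augment")
    out: List[Spectrum2D] = []
    if params.keep_original:
        out.append(spec.copy_with(is_original=True, parent_id=spec.sample_id))
    for i in range(params.factor):
        variant_id = f"{spec.sample_id}_aug{i:03d}"
        current = spec
        for k, ref in enumerate(regions):
            # re-detect on the partially augmented spectrum and track the
            # reference peak by nearest centroid (in log coordinates)
            regs = detect_peaks(current, **(detect_kw or {}))
            if not regs:
                break
            target = min(
                regs,
                key=lambda r: (np.log(r.centroid_t1 / ref.centroid_t1)) ** 2
                + (np.log(r.centroid_t2 / ref.centroid_t2)) ** 2,
            )
            for attempt in range(max_attempts):
                dt1 = rng.normal(0.0, params.shift_std_t1)
                dt2 = rng.normal(0.0, params.shift_std_t2)
                s1 = rng.normal(0.0, params.stretch_std)
                s2 = rng.normal(0.0, params.stretch_std)
                try:
                    current = _move_peak(current, target, dt1, dt2, s1, s2)
                except BoundaryError:
                    continue
                if applied_log is not None:
                    applied_log.append(
                        {
                            "sample_id": variant_id,
                            "parent_id": spec.sample_id,
                            "draw_index": i,
                            "peak_index": k,
                            "dt1": dt1,
                            "dt2": dt2,
                            "s1": s1,
                            "s2": s2,
                        }
                    )
                break
            else:
                raise BoundaryError(
                    f"could not place peak {k} of {spec.sample_id!r} "
                    f"within {max_attempts} redraws"
                )
        out.append(
            current.copy_with(
                sample_id=variant_id,
                is_original=False,
                parent_id=spec.sample_id,
            )
        )
    return out


def augment_dataset(
    spectra: Sequence[Spectrum2D],
    params: AugmentationParams,
    class_params: Optional[Dict[str, AugmentationParams]] = None,
    detect_kw: Optional[dict] = None,
) -> Tuple[List[Spectrum2D], pd.DataFrame]:
    """Augment a cohort sample-by-sample with independent derived seeds.

    ``class_params`` overrides the parameters per class label.  Returns the
    augmented cohort and a lineage manifest recording, for every output
    spectrum, its parent and whether it is the unmodified original.
    """
    ss = np.random.SeedSequence(params.seed)
    child_seeds = ss.spawn(len(spectra))
    out: List[Spectrum2D] = []
    rows = []
    for spec, child in zip(spectra, child_seeds):
        p = (class_params or {}).get(spec.class_label, params)
        applied: list = []
        variants = augment_spectrum(
            spec, p, rng=np.random.default_rng(child), detect_kw=detect_kw,
            applied_log=applied,
        )
        by_variant: Dict[str, list] = {}
        for a in applied:
            by_variant.setdefault(a["sample_id"], []).append(a)
        for v in variants:
            out.append(v)
            draws = by_variant.get(v.sample_id, [])
            rows.append(
                {
                    "sample_id": v.sample_id,
                    "parent_id": spec.sample_id,
                    "class_label": v.class_label,
                    "is_original": v.is_original,
                    "applied_dt1": draws[0]["dt1"] if draws else 0.0,
                    "applied_dt2": draws[0]["dt2"] if draws else 0.0,
                    "applied_s1": draws[0]["s1"] if draws else 0.0,
                    "applied_s2": draws[0]["s2"] if draws else 0.0,
                    "n_peaks_moved": len(draws),
                }
            )
    return out, pd.DataFrame(rows)
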