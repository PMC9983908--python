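"""The 2D T1/T2 spectrum: a nonnegative intensity map on log-spaced grids.

This is the central object of the pipeline: the output of the regularized
inverse Laplace transform, the input of peak detection, augmentation and
the CNN classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

__all__ = ["Spectrum2D", "log_grid"]


def log_grid(n: int, lo: float, hi: float) -> np.ndarray:
    """Log-spaced relaxation-time grid of ``n`` points on [lo, hi] seconds."""
    if n < 2 or not (0 < lo < hi):
        raise ValueError("need n >= 2 and 0 < lo < hi")
    return np.geomspace(lo, hi, n)


@dataclass
class Spectrum2D:
    """Joint T1/T2 intensity distribution.

    ``intensity[i, j]`` is the (nonnegative) amplitude at ``t1_grid[i]``,
    ``t2_grid[j]``.
    """

    t1_grid: np.ndarray
    t2_grid: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    phenotype: str = ""
    class_label: str = ""
    alpha: float = 0.0
    residual_norm: float = 0.0
    is_original: bool = True  # False for augmentation products
    parent_id: str = ""

    def __post_init__(self) -> None:
        self.t1_grid = np.asarray(self.t1_grid, dtype=float)
        self.t2_grid = np.asarray(self.t2_grid, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.t1_grid.size, self.t2_grid.size):
            raise ValueError("intensity shape does not match grids")
        if not (np.all(np.diff(self.t1_grid) > 0) and np.all(np.diff(self.t2_grid) > 0)):
            raise ValueError("grids must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be nonnegative")
        if not np.isfinite(self.intensity).all():
            raise ValueError("intensity must be finite")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.intensity.shape

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())

    def copy_with(self, **kwargs) -> "Spectrum2D":
        base = dict(
            t1_grid=self.t1_grid.copy(),
            t2_grid=self.t2_grid.copy(),
            intensity=self.intensity.copy(),
            sample_id=self.sample_id,
            phenotype=self.phenotype,
            class_label=self.class_label,
            alpha=self.alpha,
            residual_norm=self.residual_norm,
            is_original=self.is_original,
            parent_id=self.parent_id,
        )
        base.update(kwargs)
        return Spectrum2D(**base)

    def crop(self, t1_max: float, t2_max: float, t1_min: float = 0.0, t2_min: float = 0.0) -> "Spectrum2D":
        """Restrict to the window ``t1 in [t1_min, t1_max]``, ``t2 in
        [t2_min, t2_max]``; raises if the window misses the grid."""
        m1 = (self.t1_grid >= t1_min) & (self.t1_grid <= t1_max)
        m2 = (self.t2_grid >= t2_min) & (self.t2_grid <= t2_max)
        if not (m1.any() and m2.any()):
            raise ValueError("crop window does not overlap the grid")
        return self.copy_with(
            t1_grid=self.t1_grid[m1],
            t2_grid=self.t2_grid[m2],
            intensity=self.intensity[np.ix_(m1, m2)],
        )

    def to_image(self, size: Optional[Tuple[int, int]] = None) -> np.ndarray:
        """Max-normalized intensity map in [0, 1], T1 on rows ascending
        downward, optionally resampled to ``size`` (rows, cols)."""
        img = self.intensity
        peak = img.max()
        img = img / peak if peak > 0 else img
        if size is not None and size != img.shape:
            from scipy.ndimage import zoom

            factors = (size[0] / img.shape[0], size[1] / img.shape[1])
            img = np.clip(zoom(img, factors, order=1), 0.0, None)
            peak = img.max()
            if peak > 0:
                img = img / peak
        return img

    def plot(self, ax=None, log_axes: bool = True, **contour_kw):
        """Contour plot of the spectrum with T2 on x and T1 on y."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.contourf(self.t2_grid, self.t1_grid, self.intensity, **contour_kw)
        if log_axes:
            ax.set_xscale("log")
            ax.set_yscale("log")
        ax.set_xlabel("T2 (s)")
        ax.set_ylabel("T1 (s)")
        ax.set_title(self.sample_id)
        return ax
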