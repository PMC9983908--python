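"""Post-processing of raw IR-CPMG data before spectral inversion.

The chain mirrors the scanner's pipeline: collapse the intra-echo points to
one amplitude per echo, re-grid the echo train onto a logarithmic time axis
of 256 points, normalize to unit maximum amplitude, denoise with a
truncated-SVD (PCA) low-rank approximation, and fix the inversion-recovery
polarity so the longest-TI row is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .simulate import TimeDomainData

__all__ = [
    "EchoSeries",
    "collapse_echo_points",
    "regrid_log_t2",
    "normalize",
    "pca_denoise",
    "orient_t1",
    "preprocess",
]


@dataclass
class EchoSeries:
    """TI x echo-time amplitude matrix with its axes and processing metadata."""

    ti_vector: np.ndarray
    echo_times: np.ndarray
    amplitudes: np.ndarray
    sample_id: str = ""
    phenotype: str = ""
    class_label: str = ""
    scale: float = 1.0          # normalization factor removed from amplitudes
    sign_flipped: bool = False  # whether orient_t1 negated the data
    denoise_residual: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitudes.shape != (self.ti_vector.size, self.echo_times.size):
            raise ValueError("amplitude shape does not match axes")
        if not np.all(np.diff(self.echo_times) > 0):
            raise ValueError("echo_times must be strictly increasing")

    def copy_with(self, **kwargs) -> "EchoSeries":
        base = dict(
            ti_vector=self.ti_vector,
            echo_times=self.echo_times,
            amplitudes=self.amplitudes,
            sample_id=self.sample_id,
            phenotype=self.phenotype,
            class_label=self.class_label,
            scale=self.scale,
            sign_flipped=self.sign_flipped,
            denoise_residual=self.denoise_residual,
        )
        base.update(kwargs)
        return EchoSeries(**base)


def collapse_echo_points(raw: TimeDomainData) -> EchoSeries:
    """Average the digitised points of each echo into one amplitude.

    Identity on data already collapsed to one point per echo.
    """
    amps = raw.amplitudes
    if amps.ndim == 3:
        amps = amps.mean(axis=2)
    return EchoSeries(
        ti_vector=raw.ti_vector,
        echo_times=raw.echo_times,
        amplitudes=amps,
        sample_id=raw.sample_id,
        phenotype=raw.phenotype,
        class_label=raw.class_label,
    )


def regrid_log_t2(series: EchoSeries, n_out: int = 256) -> EchoSeries:
    """Re-grid the echo train onto ``n_out`` log-spaced times.

    Echoes are averaged within each log-time bin; bins that catch no echo
    are filled by linear interpolation in log time.  Bin centres are the
    log-spaced points between the first and last input echo time.
    """
    t_in = series.echo_times
    if n_out > t_in.size:
        raise ValueError(f"n_out={n_out} exceeds number of echoes {t_in.size}")
    t_out = np.geomspace(t_in[0], t_in[-1], n_out)
    log_t = np.log(t_out)
    # bin edges at midpoints in log time
    edges = np.empty(n_out + 1)
    edges[1:-1] = 0.5 * (log_t[:-1] + log_t[1:])
    edges[0] = -np.inf
    edges[-1] = np.inf
    idx = np.searchsorted(edges, np.log(t_in), side="right") - 1
    counts = np.bincount(idx, minlength=n_out)
    amps_out = np.zeros((series.amplitudes.shape[0], n_out))
    for i in range(series.amplitudes.shape[0]):
        sums = np.bincount(idx, weights=series.amplitudes[i], minlength=n_out)
        with np.errstate(invalid="ignore"):
            row = sums / counts
        if (counts == 0).any():
            filled = counts > 0
            row = np.interp(log_t, log_t[filled], row[filled])
        amps_out[i] = row
    return series.copy_with(echo_times=t_out, amplitudes=amps_out)


def normalize(series: EchoSeries) -> EchoSeries:
    """Divide by the maximum absolute amplitude; the scale is retained in
    metadata so the operation can be undone."""
    peak = float(np.max(np.abs(series.amplitudes)))
    if peak == 0:
        raise ValueError("cannot normalize all-zero data")
    return series.copy_with(amplitudes=series.amplitudes / peak, scale=series.scale * peak)


def pca_denoise(series: EchoSeries, rank: int = 8) -> EchoSeries:
    """Replace the amplitude matrix by its best rank-``rank`` approximation.

    The IR-CPMG signal of a p-component sample is a rank-p matrix (outer
    products of T1-recovery and T2-decay profiles), so a small rank keeps
    the signal and discards most of the noise.
    """
    m = min(series.amplitudes.shape)
    if not (1 <= rank <= m):
        raise ValueError(f"rank must be in [1, {m}], got {rank}")
    u, s, vt = np.linalg.svd(series.amplitudes, full_matrices=False)
    approx = (u[:, :rank] * s[:rank]) @ vt[:rank]
    residual = float(np.linalg.norm(series.amplitudes - approx))
    return series.copy_with(amplitudes=approx, denoise_residual=residual)


def orient_t1(series: EchoSeries) -> EchoSeries:
    """Apply the global sign convention of inversion recovery.

    The acquired phase is arbitrary up to a global sign; the convention is
    that the fully recovered (longest-TI) row is positive on average, which
    leaves rows before the inversion null negative at early echo times.
    """
    flip = float(series.amplitudes[-1].mean()) < 0
    if flip:
        return series.copy_with(amplitudes=-series.amplitudes, sign_flipped=True)
    return series


def preprocess(
    raw: TimeDomainData,
    n_t2: int = 256,
    denoise_rank: Optional[int] = 8,
) -> EchoSeries:
    """Full chain: collapse, log re-grid, normalize, PCA denoise, orient."""
    series = collapse_echo_points(raw)
    series = regrid_log_t2(series, n_out=n_t2)
    series = normalize(series)
    if denoise_rank:
        series = pca_denoise(series, rank=denoise_rank)
    return orient_t1(series)
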