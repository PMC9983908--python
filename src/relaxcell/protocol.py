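"""Acquisition protocol for the IR-CPMG relaxometry experiment.

The experiment interleaves an inversion-recovery preparation (a 180° pulse
followed, after an inversion time TI, by a 90° readout) with a CPMG echo
train whose echo amplitudes decay with T2.  One acquisition therefore spans
a grid of inversion times times echo times, and each echo is digitised with
a fixed number of points.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AcquisitionProtocol",
    "default_protocol",
    "log_spaced_inversion_times",
]


def log_spaced_inversion_times(n: int, tmin: float, tmax: float) -> np.ndarray:
    """Geometrically spaced inversion times from ``tmin`` to ``tmax`` inclusive.

    Parameters
    ----------
    n : int
        Number of inversion times, at least 2.
    tmin, tmax : float
        First and last inversion time in seconds, ``0 < tmin < tmax``.

    Returns
    -------
    numpy.ndarray
        Strictly increasing vector of length ``n`` whose consecutive ratios
        are constant.
    """
    if n < 2:
        raise ValueError(f"need at least 2 inversion times, got {n}")
    if not (0 < tmin < tmax):
        raise ValueError(f"require 0 < tmin < tmax, got tmin={tmin}, tmax={tmax}")
    ti = np.geomspace(tmin, tmax, n)
    # pin the endpoints exactly; geomspace can be off in the last ulp
    ti[0] = tmin
    ti[-1] = tmax
    return ti


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing and dimensions of one IR-CPMG acquisition.

    Attributes
    ----------
    n_inversions : int
        Number of inversion times (TI steps).
    ti_min, ti_max : float
        First and last inversion time, seconds; TI is log-spaced between them.
    n_echoes : int
        Number of refocusing pulses in the CPMG train.
    echo_spacing_te : float
        Inter-echo time TE in seconds; echo ``j`` occurs at ``(j + 1) * TE``.
    points_per_echo : int
        Digitised samples per echo.
    noise_sigma : float
        Standard deviation of additive Gaussian noise, in units of the unit
        equilibrium magnetization.
    seed : int
        Default seed for simulations using this protocol.
    """

    n_inversions: int = 32
    ti_min: float = 0.005
    ti_max: float = 15.0
    ti_spacing: str = "logarithmic"
    n_echoes: int = 5000
    echo_spacing_te: float = 0.003
    points_per_echo: int = 40
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ti_min <= 0:
            raise ValueError("ti_min must be positive")
        if self.ti_max <= self.ti_min:
            raise ValueError("ti_max must exceed ti_min")
        if self.n_inversions < 2:
            raise ValueError("n_inversions must be >= 2")
        if self.n_echoes < 2:
            raise ValueError("n_echoes must be >= 2")
        if self.echo_spacing_te <= 0:
            raise ValueError("echo_spacing_te must be positive")
        if self.points_per_echo < 1:
            raise ValueError("points_per_echo must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.ti_spacing != "logarithmic":
            raise ValueError("only logarithmic TI spacing is supported")

    @property
    def ti_vector(self) -> np.ndarray:
        """Inversion times in seconds, log-spaced from ti_min to ti_max."""
        return log_spaced_inversion_times(self.n_inversions, self.ti_min, self.ti_max)

    @property
    def echo_times(self) -> np.ndarray:
        """Echo-top times in seconds: TE, 2 TE, ..., n_echoes * TE."""
        return self.echo_spacing_te * np.arange(1, self.n_echoes + 1)

    def with_(self, **kwargs) -> "AcquisitionProtocol":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def default_protocol(**overrides) -> AcquisitionProtocol:
    """The benchtop scanner protocol: 32 TIs from 5 ms to 15 s, a 5000-echo
    CPMG train at TE = 3 ms, 40 points per echo."""
    return AcquisitionProtocol(**overrides)
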