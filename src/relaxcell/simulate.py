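"""Forward model of the IR-CPMG experiment.

The ideal-pulse signal of a single relaxation site (T1, T2) with amplitude
M0 measured at inversion time TI and echo time t is

    S(TI, t) = M0 * (1 - 2 * exp(-TI / T1)) * exp(-t / T2)

(inversion efficiency fixed at 2, i.e. an ideal 180° pulse).  A sample's
signal is the superposition of its components' signals, with per-replicate
log-normal jitter on each component's (T1, T2) and additive i.i.d. Gaussian
noise on every digitised point.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping

import numpy as np

from .phenotypes import CohortManifest, RelaxationComponent, RelaxationPhenotype
from .protocol import AcquisitionProtocol

__all__ = [
    "TimeDomainData",
    "ir_cpmg_amplitude",
    "simulate_sample",
    "simulate_cohort",
]


@dataclass
class TimeDomainData:
    """One acquired sample: echo amplitudes over the TI x echo-time grid.

    ``amplitudes`` has shape (n_inversions, n_echoes) after echo-point
    collapse, or (n_inversions, n_echoes, points_per_echo) raw.
    """

    ti_vector: np.ndarray
    echo_times: np.ndarray
    amplitudes: np.ndarray
    sample_id: str = ""
    phenotype: str = ""
    class_label: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.ti_vector) > 0):
            raise ValueError("ti_vector must be strictly increasing")
        if not np.all(np.diff(self.echo_times) > 0):
            raise ValueError("echo_times must be strictly increasing")

    @property
    def is_raw(self) -> bool:
        return self.amplitudes.ndim == 3


def ir_cpmg_amplitude(ti, t, component: RelaxationComponent):
    """Noise-free IR-CPMG amplitude of one component.

    Broadcasts over array-valued ``ti`` and ``t``.
    """
    ti = np.asarray(ti, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(ti <= 0):
        raise ValueError("inversion time must be positive")
    if np.any(t < 0):
        raise ValueError("echo time must be >= 0")
    out = component.amplitude * (1.0 - 2.0 * np.exp(-ti / component.t1)) * np.exp(-t / component.t2)
    return out if out.ndim else float(out)


def _jittered(component: RelaxationComponent, rng: np.random.Generator) -> RelaxationComponent:
    """Draw this replicate's realised (T1, T2) from the log-normal jitter."""
    t1 = component.t1 * 10.0 ** (rng.normal(0.0, component.jitter_log_t1)) if component.jitter_log_t1 else component.t1
    t2 = component.t2 * 10.0 ** (rng.normal(0.0, component.jitter_log_t2)) if component.jitter_log_t2 else component.t2
    return RelaxationComponent(t1, t2, component.amplitude)


def simulate_sample(
    phenotype: RelaxationPhenotype,
    protocol: AcquisitionProtocol,
    seed: int,
    raw: bool = False,
    sample_id: str = "",
    class_label: str = "",
) -> TimeDomainData:
    """Simulate one acquisition of ``phenotype`` under ``protocol``.

    Component positions are jittered once per sample; noise is i.i.d.
    Gaussian with std ``protocol.noise_sigma`` on every digitised point.
    With ``raw=True`` the 40 intra-echo points are returned (the echo
    amplitude replicated, each point with independent noise); otherwise
    points are already averaged so the per-echo noise std is
    ``noise_sigma / sqrt(points_per_echo)``.
    """
    rng = np.random.default_rng(seed)
    ti = protocol.ti_vector
    t = protocol.echo_times
    signal = np.zeros((ti.size, t.size))
    for comp in phenotype.components:
        realised = _jittered(comp, rng)
        signal += ir_cpmg_amplitude(ti[:, None], t[None, :], realised)
    sigma = protocol.noise_sigma
    if raw:
        amps = np.repeat(signal[:, :, None], protocol.points_per_echo, axis=2)
        if sigma > 0:
            amps = amps + rng.normal(0.0, sigma, amps.shape)
    else:
        amps = signal
        if sigma > 0:
            amps = amps + rng.normal(
                0.0, sigma / np.sqrt(protocol.points_per_echo), amps.shape
            )
    return TimeDomainData(
        ti_vector=ti,
        echo_times=t,
        amplitudes=amps,
        sample_id=sample_id or phenotype.name,
        phenotype=phenotype.name,
        class_label=class_label,
        seed=seed,
    )


def replicate_seeds(root_seed: int, n: int) -> np.ndarray:
    """Deterministic per-replicate seeds derived from one root seed."""
    ss = np.random.SeedSequence(root_seed)
    return np.array([int(s) % (2**31 - 1) for s in ss.generate_state(n)], dtype=np.int64)


def simulate_cohort(
    manifest: CohortManifest,
    phenotypes: Mapping[str, RelaxationPhenotype],
    protocol: AcquisitionProtocol,
    raw: bool = False,
) -> List[TimeDomainData]:
    """Simulate every replicate listed in the manifest.

    Emits exactly ``sum(n_replicates)`` samples; per-sample seeds derive
    deterministically from each manifest row's seed.
    """
    out: List[TimeDomainData] = []
    for row in manifest.rows.itertuples(index=False):
        if row.phenotype not in phenotypes:
            raise KeyError(f"phenotype {row.phenotype!r} not in library")
        pheno = phenotypes[row.phenotype]
        row_tag = zlib.crc32(str(row.sample_id).encode()) % (2**20)
        seeds = replicate_seeds(int(row.seed) + row_tag, int(row.n_replicates))
        for r, s in enumerate(seeds):
            out.append(
                simulate_sample(
                    pheno,
                    protocol,
                    seed=int(s),
                    raw=raw,
                    sample_id=f"{row.sample_id}_{r:03d}",
                    class_label=str(row.class_label),
                )
            )
    return out
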