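"""Shared fixtures: reduced-size protocols and synthetic blob spectra.

Everything is generated programmatically; reduced echo counts and grids
keep the suite fast while preserving the physics (the full-size defaults
are exercised in the protocol/kernel unit tests).
"""

import numpy as np
import pytest

from relaxcell import Spectrum2D, default_protocol
from relaxcell.spectrum import log_grid


@pytest.fixture(scope="session")
def fast_protocol():
    """Reduced acquisition: 32 TIs x 400 echoes, collapsed points, no noise."""
    return default_protocol(n_echoes=400, points_per_echo=1, noise_sigma=0.0)


@pytest.fixture(scope="session")
def noisy_protocol():
    """Reduced acquisition at SNR 100 on the first echo."""
    return default_protocol(n_echoes=400, points_per_echo=1, noise_sigma=0.01)


@pytest.fixture(scope="session")
def grids():
    """64x64 log-spaced T1/T2 grids over the default bounds."""
    return log_grid(64, 1e-3, 15.0), log_grid(64, 1e-3, 5.0)


@pytest.fixture
def make_blob_spectrum(grids):
    """Factory for spectra made of log-normal blobs.

    ``blobs`` is a list of (t1_center, t2_center, amplitude); ``width`` is
    the common std in natural-log units.
    """
    t1g, t2g = grids

    def build(blobs, width=0.18, sample_id="blob", class_label=""):
        X, Y = np.log(t1g)[:, None], np.log(t2g)[None, :]
        inten = np.zeros((t1g.size, t2g.size))
        for c1, c2, amp in blobs:
            inten += amp * np.exp(
                -((X - np.log(c1)) ** 2 + (Y - np.log(c2)) ** 2) / (2 * width**2)
            )
        return Spectrum2D(t1g, t2g, inten, sample_id=sample_id, class_label=class_label)

    return build


@pytest.fixture
def cell_media_spectrum(make_blob_spectrum):
    """Typical cell sample: cell peak (0.5 s, 0.05 s) + media peak (2.5 s, 1.5 s)."""
    return make_blob_spectrum([(0.5, 0.05, 1.0), (2.5, 1.5, 0.5)], sample_id="cell")
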