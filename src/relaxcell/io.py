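"""Serialization of pipeline artifacts.

Spectra travel as long-format CSV (t1, t2, intensity) or 8-bit grayscale
PNG (the CNN input format); centroid tables, manifests and reports as CSV;
provenance as JSON.  The CSV readers sniff headers so locally supplied
spectral/centroid tables in the same layout can be fed into classification
directly.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .features import CentroidRecord
from .preprocess import EchoSeries
from .simulate import TimeDomainData
from .spectrum import Spectrum2D

__all__ = [
    "write_spectrum_csv",
    "read_spectrum_csv",
    "write_png",
    "read_png",
    "read_centroids_csv",
    "write_centroids_csv",
    "write_timedomain_csv",
    "read_timedomain_csv",
    "write_provenance",
]

_FMT = "%.9g"  # lossless enough for float32-scale data, stable round-trip


def write_spectrum_csv(spec: Spectrum2D, path) -> None:
    """Long-format export: one row per grid cell (t1, t2, intensity)."""
    tt1, tt2 = np.meshgrid(spec.t1_grid, spec.t2_grid, indexing="ij")
    frame = pd.DataFrame(
        {"t1": tt1.ravel(), "t2": tt2.ravel(), "intensity": spec.intensity.ravel()}
    )
    frame.to_csv(path, index=False, float_format=_FMT)


def read_spectrum_csv(path, **meta) -> Spectrum2D:
    """Read a long-format spectral CSV back into a :class:`Spectrum2D`.

    Column names are matched case-insensitively with fallbacks for T1/T2
    spellings; malformed rows raise with the offending line number.
    """
    try:
        frame = pd.read_csv(path)
    except (pd.errors.ParserError, ValueError) as err:
        raise ValueError(f"malformed spectral CSV {path}: {err}") from err
    cols = {c.lower().strip(): c for c in frame.columns}

    def pick(*names):
        for n in names:
            if n in cols:
                return cols[n]
        raise ValueError(f"{path}: no column matching {names}; found {list(frame.columns)}")

    c1, c2, ci = pick("t1", "t_1"), pick("t2", "t_2"), pick("intensity", "value", "amplitude")
    bad = frame[[c1, c2, ci]].isna().any(axis=1)
    if bad.any():
        raise ValueError(f"{path}: malformed row at line {int(bad.idxmax()) + 2}")
    t1 = np.unique(frame[c1].to_numpy(float))
    t2 = np.unique(frame[c2].to_numpy(float))
    inten = np.full((t1.size, t2.size), np.nan)
    i = np.searchsorted(t1, frame[c1].to_numpy(float))
    j = np.searchsorted(t2, frame[c2].to_numpy(float))
    inten[i, j] = frame[ci].to_numpy(float)
    if np.isnan(inten).any():
        raise ValueError(f"{path}: spectral CSV does not cover a full t1 x t2 grid")
    return Spectrum2D(t1_grid=t1, t2_grid=t2, intensity=np.clip(inten, 0.0, None), **meta)


def write_png(spec: Spectrum2D, path) -> None:
    """8-bit grayscale export, max-normalized per spectrum, T1 on rows
    ascending downward (the layout consumed by the CNN)."""
    img = (np.clip(spec.to_image(), 0.0, 1.0) * 255.0).round().astype(np.uint8)
    Image.fromarray(img, mode="L").save(path)


def read_png(path, t1_grid: Optional[np.ndarray] = None, t2_grid: Optional[np.ndarray] = None, **meta) -> Spectrum2D:
    """Read a grayscale spectral map; grids default to unit-normalized
    log-spaced axes when the true axes are unknown (sufficient for
    classification, which only uses the image)."""
    img = np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0
    n1, n2 = img.shape
    if t1_grid is None:
        t1_grid = np.geomspace(1e-3, 15.0, n1)
    if t2_grid is None:
        t2_grid = np.geomspace(1e-3, 5.0, n2)
    return Spectrum2D(t1_grid=np.asarray(t1_grid), t2_grid=np.asarray(t2_grid), intensity=img, **meta)


def write_centroids_csv(records: Sequence[CentroidRecord], path) -> None:
    pd.DataFrame(
        [(r.sample_id, r.class_label, r.t1, r.t2) for r in records],
        columns=["sample_id", "class_label", "t1", "t2"],
    ).to_csv(path, index=False, float_format=_FMT)


def read_centroids_csv(path) -> List[CentroidRecord]:
    """Schema-tolerant centroid reader: accepts any table carrying a class
    label column and T1/T2 columns under common spellings."""
    frame = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in frame.columns}

    def pick(*names, required=True):
        for n in names:
            if n in cols:
                return cols[n]
        if required:
            raise ValueError(f"{path}: no column matching {names}; found {list(frame.columns)}")
        return None

    c_t1 = pick("t1", "t_1", "centroid_t1", "t1_s")
    c_t2 = pick("t2", "t_2", "centroid_t2", "t2_s")
    c_cls = pick("class_label", "class", "label", "celltype", "cell_type", "cell_line")
    c_id = pick("sample_id", "sample", "id", "name", required=False)
    records = []
    for n, row in enumerate(frame.itertuples(index=False)):
        d = row._asdict()
        try:
            records.append(
                CentroidRecord(
                    sample_id=str(d[c_id]) if c_id else f"sample_{n:04d}",
                    class_label=str(d[c_cls]),
                    t1=float(d[c_t1]),
                    t2=float(d[c_t2]),
                )
            )
        except (TypeError, ValueError) as err:
            raise ValueError(f"{path}: malformed row at line {n + 2}: {err}") from err
    return records


def write_timedomain_csv(data: TimeDomainData, path) -> None:
    """One file per sample: ti_index, echo_index, amplitude (collapsed)."""
    amps = data.amplitudes if data.amplitudes.ndim == 2 else data.amplitudes.mean(axis=2)
    ii, jj = np.meshgrid(np.arange(amps.shape[0]), np.arange(amps.shape[1]), indexing="ij")
    pd.DataFrame(
        {"ti_index": ii.ravel(), "echo_index": jj.ravel(), "amplitude": amps.ravel()}
    ).to_csv(path, index=False, float_format=_FMT)


def read_timedomain_csv(path, ti_vector: np.ndarray, echo_times: np.ndarray, **meta) -> TimeDomainData:
    frame = pd.read_csv(path)
    n_ti, n_echo = int(frame["ti_index"].max()) + 1, int(frame["echo_index"].max()) + 1
    amps = np.zeros((n_ti, n_echo))
    amps[frame["ti_index"], frame["echo_index"]] = frame["amplitude"]
    return TimeDomainData(
        ti_vector=np.asarray(ti_vector), echo_times=np.asarray(echo_times), amplitudes=amps, **meta
    )


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_provenance(path, config: dict, seed: int, extra: Optional[dict] = None) -> dict:
    """Record what produced a run's artifacts: config hash, seed, versions."""
    import relaxcell

    record = {
        "config_hash": config_hash(config),
        "config": config,
        "seed": seed,
        "package_version": relaxcell.__version__,
        "python_version": platform.python_version(),
        "numpy_version": np.__version__,
    }
    if extra:
        record.update(extra)
    Path(path).write_text(json.dumps(record, indent=2, default=str))
    return record
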