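"""End-to-end orchestration: simulate -> reconstruct -> features ->
augment -> classify, as seeded, reproducible runs.

A run is configured by :class:`RunConfig`, which scales the whole pipeline
coherently: the ``full`` preset uses the complete acquisition (5000 echoes,
300x300 spectra, the 369-sample cohort composition), the ``reduced`` preset
the sizes used for routine validation, and ``smoke`` a minutes-scale
check.  All randomness flows from one root seed through named substreams.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import io as rio
from .augment import CELL_LINE_PRESET, MSC_PRESET, AugmentationParams, augment_dataset
from .classify import (
    AnnArchitecture,
    CentroidSVM,
    SplitSpec,
    SpectralCNN,
    SvmConfig,
)
from .features import centroid_table
from .ilt import SpectrumModel
from .phenotypes import CohortManifest, default_phenotype_library, reference_cohort_manifest
from .preprocess import preprocess
from .protocol import AcquisitionProtocol, default_protocol
from .simulate import simulate_cohort
from .spectrum import Spectrum2D

__all__ = ["RunConfig", "Pipeline", "reconstruct_spectrum"]

logger = logging.getLogger(__name__)


def _stream_seed(root: int, name: str) -> int:
    """Named deterministic substream of the root seed."""
    return int(np.random.SeedSequence([root, zlib.crc32(name.encode())]).generate_state(1)[0]) % (
        2**31 - 1
    )


@dataclass
class RunConfig:
    """All knobs of one pipeline run, grouped by stage."""

    seed: int = 0
    # protocol
    n_echoes: int = 5000
    points_per_echo: int = 40
    noise_sigma: float = 0.01
    # reconstruction
    n_t2_regrid: int = 256
    grid_n: int = 300
    denoise_rank: int = 8
    alpha: Optional[float] = None  # None -> discrepancy principle
    compress: Tuple[int, int] = (16, 32)
    # cohort
    manifest_variant: str = "full"
    replicate_scale: float = 1.0  # scales every manifest count (min 3)
    phenotype_subset: Optional[Tuple[str, ...]] = None
    # features
    threshold_frac: float = 0.05
    # augmentation / classifiers
    augmentation_factor: int = 5
    ann_input: Tuple[int, int] = (64, 64)
    ann_base_channels: int = 16
    ann_dense: Tuple[int, int, int] = (256, 128, 64)
    svm_replicates: int = 300
    ann_replicates: int = 10
    epochs: int = 12

    @classmethod
    def preset(cls, name: str, seed: int = 0) -> "RunConfig":
        if name == "full":
            return cls(seed=seed)
        if name == "reduced":
            return cls(
                seed=seed, n_echoes=1000, points_per_echo=1, n_t2_regrid=128,
                grid_n=100, replicate_scale=0.25, ann_input=(32, 32), alpha=1e-3,
                ann_base_channels=8, ann_dense=(64, 32, 16), svm_replicates=50,
            )
        if name == "smoke":
            return cls(
                seed=seed, n_echoes=400, points_per_echo=1, n_t2_regrid=96,
                grid_n=64, replicate_scale=0.0, ann_input=(16, 16), alpha=1e-3,
                ann_base_channels=4, ann_dense=(32, 16, 8), svm_replicates=20,
                ann_replicates=2, epochs=6,
                phenotype_subset=(
                    "CHO", "K562", "MDA231", "HeLa", "MSC_undiff", "MSC_diff"
                ),
            )
        raise ValueError(f"unknown preset {name!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh)
        cfg = cls(**payload)
        for f in ("compress", "ann_input", "ann_dense", "phenotype_subset"):
            value = getattr(cfg, f)
            if value is not None:
                setattr(cfg, f, tuple(value))
        return cfg

    @property
    def protocol(self) -> AcquisitionProtocol:
        return default_protocol(
            n_echoes=self.n_echoes,
            points_per_echo=self.points_per_echo,
            noise_sigma=self.noise_sigma,
        )

    def manifest(self) -> CohortManifest:
        mani = reference_cohort_manifest(
            variant=self.manifest_variant, seed=_stream_seed(self.seed, "simulate")
        )
        rows = mani.rows
        if self.phenotype_subset is not None:
            rows = rows[rows["phenotype"].isin(self.phenotype_subset)].reset_index(drop=True)
        if self.replicate_scale != 1.0:
            rows = rows.copy()
            scale = self.replicate_scale if self.replicate_scale > 0 else 0.0
            rows["n_replicates"] = np.maximum(
                3, np.round(rows["n_replicates"] * scale).astype(int)
            )
        return CohortManifest(rows)


def reconstruct_spectrum(raw, cfg: RunConfig) -> Spectrum2D:
    """Preprocess one acquisition and invert it onto the T1/T2 grid."""
    series = preprocess(raw, n_t2=cfg.n_t2_regrid, denoise_rank=cfg.denoise_rank)
    model = SpectrumModel(series, n_t1=cfg.grid_n, n_t2=cfg.grid_n, compress=cfg.compress)
    noise = cfg.noise_sigma / (np.sqrt(cfg.points_per_echo) * series.scale)
    return model.fit(alpha=cfg.alpha, noise_sigma=noise if cfg.alpha is None else None).spectrum


class Pipeline:
    """Stage-by-stage runner holding intermediate artifacts in memory and,
    when given an output directory, writing every stage's files plus a
    provenance record."""

    def __init__(self, config: RunConfig, outdir: Optional[Path] = None):
        self.cfg = config
        self.outdir = Path(outdir) if outdir else None
        self.samples: List = []
        self.spectra: List[Spectrum2D] = []
        self.centroids: List = []
        self.exclusions: List[str] = []
        self.augmented: List[Spectrum2D] = []
        self.metrics: Dict[str, float] = {}
        self._manifest_rows: List[dict] = []
        if self.outdir:
            self.outdir.mkdir(parents=True, exist_ok=True)
            (self.outdir / "run_config.json").write_text(
                json.dumps(self.cfg.to_dict(), indent=2)
            )

    # -- dataset manifest -------------------------------------------------

    def _record(self, path: Path, sample_id: str, class_label: str, stage: str,
                parent_id: str = "", seed: int = 0) -> None:
        self._manifest_rows.append(
            {
                "path": str(path.relative_to(self.outdir)),
                "sample_id": sample_id,
                "class_label": class_label,
                "stage": stage,
                "parent_id": parent_id,
                "seed": seed,
            }
        )

    def _write_manifest(self) -> None:
        if self.outdir and self._manifest_rows:
            import pandas as pd

            pd.DataFrame(self._manifest_rows).to_csv(
                self.outdir / "manifest.csv", index=False
            )

    @classmethod
    def load(cls, outdir) -> "Pipeline":
        """Reconstitute a pipeline from a run directory: config, and every
        stage artifact listed in the dataset manifest."""
        import pandas as pd

        outdir = Path(outdir)
        cfg = RunConfig(**json.loads((outdir / "run_config.json").read_text()))
        # tuples arrive as lists from JSON
        for f in ("compress", "ann_input", "ann_dense", "phenotype_subset"):
            value = getattr(cfg, f)
            if value is not None:
                setattr(cfg, f, tuple(value))
        pipe = cls(cfg, outdir)
        mpath = outdir / "manifest.csv"
        if mpath.exists():
            mani = pd.read_csv(mpath, keep_default_na=False)
            proto = cfg.protocol
            from .preprocess import collapse_echo_points  # noqa: F401  (axes only)

            for row in mani.itertuples(index=False):
                path = outdir / row.path
                if not path.exists():
                    raise FileNotFoundError(f"manifest references missing file {path}")
                if row.stage == "raw":
                    pipe.samples.append(
                        rio.read_timedomain_csv(
                            path, proto.ti_vector, proto.echo_times,
                            sample_id=row.sample_id, class_label=row.class_label,
                        )
                    )
                elif row.stage in ("spectrum", "augmented") and path.suffix == ".csv":
                    spec = rio.read_spectrum_csv(
                        path, sample_id=row.sample_id, class_label=row.class_label,
                        parent_id=row.parent_id,
                        is_original=(row.stage == "spectrum" or "_Original" in path.name),
                    )
                    (pipe.spectra if row.stage == "spectrum" else pipe.augmented).append(spec)
            pipe._manifest_rows = mani.to_dict("records")
        cpath = outdir / "centroids.csv"
        if cpath.exists():
            pipe.centroids = rio.read_centroids_csv(cpath)
        return pipe

    def _timed(self, stage: str, fn):
        t0 = time.perf_counter()
        result = fn()
        logger.info("stage %-12s %.2f s", stage, time.perf_counter() - t0)
        return result

    def simulate(self) -> "Pipeline":
        cfg = self.cfg
        lib = default_phenotype_library()

        def run():
            return simulate_cohort(cfg.manifest(), lib, cfg.protocol)

        self.samples = self._timed("simulate", run)
        if self.outdir:
            d = self.outdir / "timedomain"
            d.mkdir(exist_ok=True)
            for s in self.samples:
                path = d / f"{s.sample_id}.csv"
                rio.write_timedomain_csv(s, path)
                self._record(path, s.sample_id, s.class_label, "raw", seed=s.seed)
            self._write_manifest()
        return self

    def reconstruct(self) -> "Pipeline":
        def run():
            return [reconstruct_spectrum(s, self.cfg) for s in self.samples]

        self.spectra = self._timed("reconstruct", run)
        if self.outdir:
            d = self.outdir / "spectra"
            d.mkdir(exist_ok=True)
            for sp in self.spectra:
                path = d / f"{sp.sample_id}.csv"
                rio.write_spectrum_csv(sp, path)
                rio.write_png(sp, d / f"{sp.sample_id}.png")
                self._record(path, sp.sample_id, sp.class_label, "spectrum")
            self._write_manifest()
        return self

    def features(self) -> "Pipeline":
        def run():
            excl: List[str] = []
            recs = centroid_table(
                self.spectra, exclusions=excl, threshold_frac=self.cfg.threshold_frac
            )
            return recs, excl

        self.centroids, self.exclusions = self._timed("features", run)
        if self.outdir:
            rio.write_centroids_csv(self.centroids, self.outdir / "centroids.csv")
            (self.outdir / "exclusions.txt").write_text("\n".join(self.exclusions))
        return self

    def augment(self, params: Optional[AugmentationParams] = None) -> "Pipeline":
        cfg = self.cfg
        params = params or dataclasses.replace(
            CELL_LINE_PRESET, factor=cfg.augmentation_factor,
            seed=_stream_seed(cfg.seed, "augment"),
        )
        class_params = {
            label: dataclasses.replace(
                MSC_PRESET, factor=cfg.augmentation_factor,
                seed=_stream_seed(cfg.seed, "augment"),
            )
            for label in ("MSC_undiff", "MSC_diff")
        }

        def run():
            return augment_dataset(
                self.spectra, params, class_params=class_params,
                detect_kw={"threshold_frac": cfg.threshold_frac},
            )

        self.augmented, lineage = self._timed("augment", run)
        if self.outdir:
            d = self.outdir / "augmented"
            d.mkdir(exist_ok=True)
            lineage.to_csv(self.outdir / "lineage.csv", index=False)
            for sp in self.augmented:
                suffix = "_Original" if sp.is_original else ""
                path = d / f"{sp.sample_id}{suffix}.csv"
                rio.write_png(sp, d / f"{sp.sample_id}{suffix}.png")
                rio.write_spectrum_csv(sp, path)
                self._record(
                    path, sp.sample_id, sp.class_label, "augmented",
                    parent_id=sp.parent_id,
                )
            self._write_manifest()
        return self

    def train_svm(self, labels: Optional[Sequence[str]] = None) -> "Pipeline":
        cfg = self.cfg
        recs = self.centroids
        if labels:
            recs = [r for r in recs if r.class_label in labels]
        # peak-detection exclusions can leave a class with too few records
        # for a 50/50 split; such classes are dropped with a warning
        from collections import Counter

        counts = Counter(r.class_label for r in recs)
        small = {c for c, n in counts.items() if n < 2}
        if small:
            logger.warning("dropping under-represented classes from SVM: %s", sorted(small))
            recs = [r for r in recs if r.class_label not in small]
        svm = CentroidSVM(
            recs,
            SvmConfig(replicates=cfg.svm_replicates, seed=_stream_seed(cfg.seed, "svm")),
        )
        res = self._timed("train-svm", svm.fit)
        self.metrics["svm_mean_accuracy"] = res.mean_accuracy
        self.metrics["svm_std_accuracy"] = res.std_accuracy
        self.svm_results = res
        if self.outdir:
            (self.outdir / "svm_report.json").write_text(
                json.dumps(
                    {
                        "mean_accuracy": res.mean_accuracy,
                        "std_accuracy": res.std_accuracy,
                        "replicates": int(res.accuracies.size),
                        "classes": res.classes,
                    },
                    indent=2,
                )
            )
        return self

    def train_ann(
        self, variant: str = "cell_line", labels: Optional[Sequence[str]] = None
    ) -> "Pipeline":
        cfg = self.cfg
        pool = self.augmented or self.spectra
        if labels:
            pool = [sp for sp in pool if sp.class_label in labels]
        arch = AnnArchitecture(
            variant=variant, epochs=cfg.epochs, input_size=cfg.ann_input,
            base_channels=cfg.ann_base_channels, dense_widths=cfg.ann_dense,
        )
        cnn = SpectralCNN(pool, arch, SplitSpec())

        def run():
            return cnn.fit(seed=_stream_seed(cfg.seed, "ann"), n_replicates=cfg.ann_replicates)

        report = self._timed("train-ann", run)
        acc = report.mean_accuracy if hasattr(report, "mean_accuracy") else report.test_accuracy
        self.metrics[f"ann_{variant}_accuracy"] = float(acc)
        self.ann_report = report
        if self.outdir:
            payload = {
                "variant": variant,
                "accuracy": float(acc),
            }
            if hasattr(report, "std_accuracy"):
                payload["std_accuracy"] = report.std_accuracy
                payload["mean_confusion"] = np.asarray(report.mean_confusion).tolist()
            (self.outdir / f"ann_{variant}_report.json").write_text(json.dumps(payload, indent=2))
        return self

    def run_all(self) -> Dict[str, float]:
        """Full pipeline; returns the metric dictionary and (with an output
        directory) writes metrics.json plus a provenance record."""
        self.simulate().reconstruct().features().augment()
        self.train_svm()
        msc_labels = [
            label for label in ("MSC_undiff", "MSC_diff")
            if any(sp.class_label == label for sp in self.augmented)
        ]
        if len(msc_labels) == 2:
            self.train_ann(variant="msc", labels=msc_labels)
        cell_labels = sorted(
            {sp.class_label for sp in self.augmented} - {"MSC_undiff", "MSC_diff"}
        )
        if len(cell_labels) >= 2:
            self.train_ann(variant="cell_line", labels=cell_labels)
        if self.outdir:
            (self.outdir / "metrics.json").write_text(json.dumps(self.metrics, indent=2))
            rio.write_provenance(
                self.outdir / "provenance.json", self.cfg.to_dict(), self.cfg.seed
            )
        return self.metrics
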