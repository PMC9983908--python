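"""Cell-type classification from T1/T2 spectra.

Two tracks, mirroring the measurement pipeline's two feature levels:

* **SVM on weighted centroids** — a polynomial-kernel support vector
  machine (degree 2, coef0 = 0) on the (T1, T2) cell-peak centroids,
  evaluated over 300 independent 50/50 train/test splits.
* **CNN on spectral maps** — two VGG-derived convolutional networks (a
  7-conv/4-dense variant for the MSC differentiation task, a 4-conv/4-dense
  variant with 25% dropout for the cell-line task) trained with Adamax for
  12 epochs on (cropped) spectral images, using the celltype-aware
  75/20/25 train/validation/test split and ten-replicate reporting.

Both model classes follow the model/results idiom: construct from data,
``fit()`` returns a results object with estimates, uncertainties and a
``summary()`` table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import CentroidRecord, crop_to_cell_window
from .nn import (
    Adamax,
    BatchNorm,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    MaxPool2,
    ReLU,
    SequentialNet,
)
from .spectrum import Spectrum2D

__all__ = [
    "SvmConfig",
    "SplitSpec",
    "AnnArchitecture",
    "TrainingReport",
    "AggregateReport",
    "StratificationError",
    "celltype_aware_split",
    "train_svm",
    "run_svm_replicates",
    "CentroidSVM",
    "SvmResults",
    "decision_boundary_map",
    "build_ann",
    "train_ann",
    "SpectralCNN",
    "replicate_runs",
    "combination_search",
]


def _sub_seeds(seed: int, n: int) -> List[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s) % (2**31 - 1) for s in state]


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


class StratificationError(ValueError):
    """A class is too small (or alone) for the requested stratified split."""


@dataclass(frozen=True)
class SplitSpec:
    """Celltype-aware train/validation/test fractions.

    Defaults: 75% of samples form the training pool, of which 20% are held
    out for validation; the remaining 25% are the test set.  ``class_aware``
    guarantees every class at least one sample in each partition; augmented
    descendants always follow their parent sample's partition.
    """

    train_fraction: float = 0.75
    val_fraction_of_train: float = 0.20
    test_fraction: float = 0.25
    class_aware: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1 and 0 < self.test_fraction < 1):
            raise ValueError("fractions must be in (0, 1)")
        if abs(self.train_fraction + self.test_fraction - 1.0) > 1e-9:
            raise ValueError("train_fraction + test_fraction must equal 1")
        if not (0 < self.val_fraction_of_train < 1):
            raise ValueError("val_fraction_of_train must be in (0, 1)")


def _parent_of(item) -> str:
    pid = getattr(item, "parent_id", "")
    return pid or getattr(item, "sample_id", str(id(item)))


def celltype_aware_split(
    items: Sequence,
    spec: SplitSpec,
    rng: Optional[np.random.Generator] = None,
):
    """Stratified three-way split guaranteeing every class in every
    partition, with no parent leakage across partitions.

    ``items`` need ``class_label`` and (for augmented data) ``parent_id``
    attributes.  Partition sizes are rounded per class with at least one
    parent sample in each of train, validation and test; classes with fewer
    than 3 parent samples raise :class:`StratificationError`.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    by_class: Dict[str, List[str]] = {}
    items_by_parent: Dict[str, List] = {}
    for it in items:
        p = _parent_of(it)
        items_by_parent.setdefault(p, []).append(it)
        cls = str(it.class_label)
        if p not in by_class.get(cls, ()):
            by_class.setdefault(cls, []).append(p)
    if len(by_class) < 2:
        raise StratificationError("need at least 2 classes to stratify")
    train, val, test = [], [], []
    for cls in sorted(by_class):
        parents = sorted(by_class[cls])
        n = len(parents)
        if n < 3:
            raise StratificationError(f"class {cls!r} has {n} parent samples; need >= 3")
        order = rng.permutation(n)
        n_test = min(max(1, round(spec.test_fraction * n)), n - 2)
        pool = n - n_test
        n_val = min(max(1, round(spec.val_fraction_of_train * pool)), pool - 1)
        for rank, idx in enumerate(order):
            bucket = test if rank < n_test else (val if rank < n_test + n_val else train)
            bucket.extend(items_by_parent[parents[idx]])
    return train, val, test


# ---------------------------------------------------------------------------
# SVM track
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SvmConfig:
    """Polynomial-kernel SVM protocol: degree 2, coef0 0, 50/50 random
    split, 300 technical replicates.

    Features are the raw centroid coordinates in seconds.  With coef0 = 0
    the polynomial kernel is homogeneous and even, so it cannot separate
    clusters placed antipodally about the origin; centering the features
    (``standardize=True``) therefore actively hurts this kernel, and the
    default keeps the centroids in the positive quadrant as measured.
    """

    kernel: str = "poly"
    degree: int = 2
    coef0: float = 0.0
    c: float = 1.0
    gamma: str = "scale"
    train_fraction: float = 0.5
    replicates: int = 300
    standardize: bool = False
    log_features: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _centroid_xy(records: Sequence[CentroidRecord], config: SvmConfig):
    x = np.array([[r.t1, r.t2] for r in records], dtype=float)
    if config.log_features:
        x = np.log10(x)
    y = np.array([str(r.class_label) for r in records])
    return x, y


def _make_svm(config: SvmConfig):
    svc = SVC(
        kernel=config.kernel, degree=config.degree, coef0=config.coef0,
        C=config.c, gamma=config.gamma,
    )
    return make_pipeline(StandardScaler(), svc) if config.standardize else svc


def _split_5050(x, y, frac, rng):
    """Random class-stratified split at the configured training fraction."""
    classes = np.unique(y)
    train_idx, test_idx = [], []
    for cls in classes:
        idx = np.nonzero(y == cls)[0]
        idx = rng.permutation(idx)
        n_train = min(max(1, round(frac * idx.size)), idx.size - 1)
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return np.array(train_idx), np.array(test_idx)


def train_svm(records: Sequence[CentroidRecord], config: SvmConfig, seed: int = 0) -> float:
    """Fit the polynomial SVM on one random 50/50 split; returns test
    accuracy.  Raises on single-class input."""
    x, y = _centroid_xy(records, config)
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes")
    for cls, cnt in zip(*np.unique(y, return_counts=True)):
        if cnt < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
    rng = np.random.default_rng(seed)
    tr, te = _split_5050(x, y, config.train_fraction, rng)
    model = _make_svm(config)
    model.fit(x[tr], y[tr])
    return float((model.predict(x[te]) == y[te]).mean())


def run_svm_replicates(
    records: Sequence[CentroidRecord], config: SvmConfig
) -> Tuple[np.ndarray, Dict[str, float]]:
    """Accuracy over ``config.replicates`` independent splits with derived
    per-replicate seeds; returns (accuracies, {'mean', 'std'})."""
    seeds = _sub_seeds(config.seed, config.replicates)
    acc = np.array([train_svm(records, config, seed=s) for s in seeds])
    return acc, {"mean": float(acc.mean()), "std": float(acc.std(ddof=1)) if acc.size > 1 else 0.0}


@dataclass
class SvmResults:
    """Replicated-SVM results: per-replicate accuracies and a refit model
    on all data for decision-boundary inspection."""

    accuracies: np.ndarray
    mean_accuracy: float
    std_accuracy: float
    classes: List[str]
    config: SvmConfig
    full_model: object

    def decision_boundary_map(self, t1_grid: np.ndarray, t2_grid: np.ndarray) -> np.ndarray:
        """Predicted class label for every (t1, t2) grid point; shape
        (len(t1_grid), len(t2_grid))."""
        return decision_boundary_map(self.full_model, t1_grid, t2_grid, log_features=self.config.log_features)

    def summary(self) -> str:
        lines = [
            "Polynomial-kernel SVM on weighted centroids",
            "=" * 48,
            f"classes:        {', '.join(self.classes)}",
            f"replicates:     {self.accuracies.size}",
            f"split:          {self.config.train_fraction:.0%} train",
            f"mean accuracy:  {100 * self.mean_accuracy:.2f}%",
            f"std accuracy:   {100 * self.std_accuracy:.2f}%",
            f"min / max:      {100 * self.accuracies.min():.2f}% / {100 * self.accuracies.max():.2f}%",
        ]
        return "\n".join(lines)


class CentroidSVM:
    """SVM classifier of cell types from weighted-centroid features.

    Parameters
    ----------
    records : sequence of CentroidRecord
        One (T1, T2) centroid per sample with its class label.
    config : SvmConfig
        Kernel and replication protocol.
    """

    def __init__(self, records: Sequence[CentroidRecord], config: Optional[SvmConfig] = None):
        self.records = list(records)
        self.config = config or SvmConfig()
        x, y = _centroid_xy(self.records, self.config)
        if np.unique(y).size < 2:
            raise ValueError("need at least 2 classes")
        self._x, self._y = x, y

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, config: Optional[SvmConfig] = None) -> "CentroidSVM":
        """Build from a centroid table with columns sample_id, class_label,
        t1, t2 (the layout of the exported centroid CSVs)."""
        records = [
            CentroidRecord(str(r.sample_id), str(r.class_label), float(r.t1), float(r.t2))
            for r in frame.itertuples(index=False)
        ]
        return cls(records, config)

    def fit(self) -> SvmResults:
        acc, stats = run_svm_replicates(self.records, self.config)
        full = _make_svm(self.config)
        full.fit(self._x, self._y)
        return SvmResults(
            accuracies=acc,
            mean_accuracy=stats["mean"],
            std_accuracy=stats["std"],
            classes=sorted(np.unique(self._y)),
            config=self.config,
            full_model=full,
        )


def decision_boundary_map(model, t1_grid, t2_grid, log_features: bool = True) -> np.ndarray:
    """Evaluate a trained centroid classifier on a (t1, t2) grid."""
    tt1, tt2 = np.meshgrid(np.asarray(t1_grid), np.asarray(t2_grid), indexing="ij")
    pts = np.stack([tt1.ravel(), tt2.ravel()], axis=1)
    if log_features:
        pts = np.log10(pts)
    return model.predict(pts).reshape(tt1.shape)


# ---------------------------------------------------------------------------
# CNN track
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnArchitecture:
    """VGG-derived CNN layout.

    ``msc`` variant: 7 convolutional layers with normalization layers in
    between and max pooling after every other convolution starting after
    the first, then 4 dense layers.  ``cell_line`` variant: 4 convolutional
    layers each followed by normalization and max pooling, then 4 dense
    layers with 25% dropout.  Both use ReLU, a softmax head, Adamax, and
    train for 12 epochs.

    Channel widths, dense widths, learning rate and batch size are not part
    of the published layout and are configurable stand-ins.
    """

    variant: str = "msc"
    epochs: int = 12
    input_size: Tuple[int, int] = (64, 64)
    base_channels: int = 16
    dense_widths: Tuple[int, ...] = (256, 128, 64)
    learning_rate: float = 1e-3
    batch_size: int = 16

    def __post_init__(self) -> None:
        if self.variant not in ("msc", "cell_line"):
            raise ValueError("variant must be 'msc' or 'cell_line'")
        if self.epochs < 1 or self.base_channels < 1 or self.batch_size < 1:
            raise ValueError("counts must be positive")
        if len(self.dense_widths) != 3:
            raise ValueError("need 3 hidden dense widths (4 dense layers with the head)")

    @property
    def conv_layers(self) -> int:
        return 7 if self.variant == "msc" else 4

    @property
    def dense_layers(self) -> int:
        return 4

    @property
    def dropout_rate(self) -> float:
        return 0.25 if self.variant == "cell_line" else 0.0

    @property
    def n_pools(self) -> int:
        return 4


def build_ann(
    arch: AnnArchitecture,
    n_classes: int,
    input_shape: Optional[Tuple[int, int]] = None,
    seed: int = 0,
) -> SequentialNet:
    """Construct the layer stack of one architecture variant."""
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    h, w = input_shape or arch.input_size
    min_size = 2**arch.n_pools
    if h < min_size or w < min_size or h % min_size or w % min_size:
        raise ValueError(
            f"input {h}x{w} incompatible with {arch.n_pools} pooling stages "
            f"(need multiples of {min_size})"
        )
    rng = np.random.default_rng(seed)
    b = arch.base_channels
    layers: List = []
    if arch.variant == "msc":
        channels = [b, b, 2 * b, 2 * b, 4 * b, 4 * b, 8 * b]
        pool_after = {0, 2, 4, 6}  # after every other conv, starting after the first
    else:
        channels = [b, 2 * b, 4 * b, 8 * b]
        pool_after = {0, 1, 2, 3}
    c_in = 1
    for i, c_out in enumerate(channels):
        layers += [Conv2D(c_in, c_out, rng=rng), BatchNorm(c_out), ReLU()]
        if i in pool_after:
            layers.append(MaxPool2())
        c_in = c_out
    layers.append(Flatten())
    d_in = (h // 2**arch.n_pools) * (w // 2**arch.n_pools) * channels[-1]
    for width in arch.dense_widths:
        layers += [Dense(d_in, width, rng=rng), ReLU()]
        if arch.dropout_rate:
            layers.append(Dropout(arch.dropout_rate, rng=rng))
        d_in = width
    layers.append(Dense(d_in, n_classes, rng=rng))  # softmax head
    return SequentialNet(layers)


@dataclass
class TrainingReport:
    """One CNN training run: per-epoch curves, test metrics, confusion."""

    epoch_loss: List[float]
    val_accuracy: List[float]
    test_accuracy: float
    confusion: np.ndarray
    classes: List[str]
    replicate_index: int = 0
    n_train: int = 0
    n_val: int = 0
    n_test: int = 0

    def summary(self) -> str:
        lines = [
            "CNN training report",
            "=" * 48,
            f"classes:            {', '.join(self.classes)}",
            f"train / val / test: {self.n_train} / {self.n_val} / {self.n_test}",
            f"epochs:             {len(self.epoch_loss)}",
            f"final loss:         {self.epoch_loss[-1]:.4f}",
            f"final val accuracy: {100 * self.val_accuracy[-1]:.2f}%",
            f"test accuracy:      {100 * self.test_accuracy:.2f}%",
            "confusion matrix (rows = true, cols = predicted):",
            str(np.asarray(self.confusion)),
        ]
        return "\n".join(lines)


@dataclass
class AggregateReport:
    """Replicate-averaged CNN results (the ten-replicate protocol)."""

    reports: List[TrainingReport]
    mean_accuracy: float
    std_accuracy: float
    mean_confusion: np.ndarray
    mean_loss_curve: np.ndarray
    mean_val_curve: np.ndarray
    classes: List[str]

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([r.test_accuracy for r in self.reports])

    def summary(self) -> str:
        lines = [
            f"CNN aggregate over {len(self.reports)} replicates",
            "=" * 48,
            f"classes:            {', '.join(self.classes)}",
            f"mean test accuracy: {100 * self.mean_accuracy:.2f}%",
            f"std test accuracy:  {100 * self.std_accuracy:.2f}%",
            f"range:              {100 * self.accuracies.min():.2f}% - "
            f"{100 * self.accuracies.max():.2f}%",
            "mean confusion matrix:",
            str(np.round(self.mean_confusion, 2)),
        ]
        return "\n".join(lines)


def spectra_to_images(
    spectra: Sequence[Spectrum2D],
    size: Tuple[int, int],
    crop: bool = True,
) -> np.ndarray:
    """Cropped (cell-window), max-normalized, resampled image stack
    (N, H, W, 1) for the CNN."""
    imgs = []
    for s in spectra:
        s2 = crop_to_cell_window(s) if crop else s
        imgs.append(s2.to_image(size=size))
    return np.stack(imgs)[..., None]


def _accuracy(net: SequentialNet, x: np.ndarray, y: np.ndarray) -> float:
    return float((net.predict(x) == y).mean())


def train_ann(
    spectra: Sequence[Spectrum2D],
    arch: AnnArchitecture,
    split: SplitSpec,
    seed: int = 0,
    crop: bool = True,
    replicate_index: int = 0,
    images: Optional[np.ndarray] = None,
) -> TrainingReport:
    """Train one CNN replicate on spectral maps.

    Performs the celltype-aware split (augmented spectra follow their
    parents), trains ``arch.epochs`` epochs with Adamax at the configured
    batch size, and reports per-epoch cumulative loss, validation accuracy,
    test accuracy and the confusion matrix.  Deterministic given ``seed``.

    ``images`` may carry a precomputed image stack aligned with ``spectra``
    to avoid re-rasterizing across replicates.
    """
    seeds = _sub_seeds(seed, 3)
    if images is None:
        images = spectra_to_images(spectra, arch.input_size, crop=crop)
    classes = sorted({str(s.class_label) for s in spectra})
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    cls_index = {c: i for i, c in enumerate(classes)}
    labels = np.array([cls_index[str(s.class_label)] for s in spectra])
    idx = list(range(len(spectra)))

    class _Item:
        __slots__ = ("i", "class_label", "parent_id", "sample_id")

        def __init__(self, i):
            self.i = i
            self.class_label = spectra[i].class_label
            self.parent_id = spectra[i].parent_id
            self.sample_id = spectra[i].sample_id

    tr, va, te = celltype_aware_split(
        [_Item(i) for i in idx], split, rng=np.random.default_rng(seeds[0])
    )
    tr_i = np.array([it.i for it in tr])
    va_i = np.array([it.i for it in va])
    te_i = np.array([it.i for it in te])

    net = build_ann(arch, len(classes), input_shape=images.shape[1:3], seed=seeds[1])
    opt = Adamax(lr=arch.learning_rate)
    rng = np.random.default_rng(seeds[2])
    epoch_loss, val_acc = [], []
    for _epoch in range(arch.epochs):
        order = rng.permutation(tr_i.size)
        cum_loss = 0.0
        for start in range(0, order.size, arch.batch_size):
            batch = tr_i[order[start : start + arch.batch_size]]
            cum_loss += net.train_batch(images[batch], labels[batch], opt)
        epoch_loss.append(cum_loss)
        val_acc.append(_accuracy(net, images[va_i], labels[va_i]))
    pred = net.predict(images[te_i])
    conf = confusion_matrix(labels[te_i], pred, labels=np.arange(len(classes)))
    return TrainingReport(
        epoch_loss=epoch_loss,
        val_accuracy=val_acc,
        test_accuracy=float((pred == labels[te_i]).mean()),
        confusion=conf,
        classes=classes,
        replicate_index=replicate_index,
        n_train=tr_i.size,
        n_val=va_i.size,
        n_test=te_i.size,
    )


def replicate_runs(
    task: Callable[[int, int], TrainingReport], n_replicates: int = 10, seed: int = 0
) -> AggregateReport:
    """Run ``task(replicate_seed, replicate_index)`` n times and average.

    The task owns its split, so every replicate sees a fresh
    train/validation/test assignment.
    """
    seeds = _sub_seeds(seed, n_replicates)
    reports = [task(s, i) for i, s in enumerate(seeds)]
    acc = np.array([r.test_accuracy for r in reports])
    max_ep = max(len(r.epoch_loss) for r in reports)
    loss = np.array([r.epoch_loss + [np.nan] * (max_ep - len(r.epoch_loss)) for r in reports])
    val = np.array([r.val_accuracy + [np.nan] * (max_ep - len(r.val_accuracy)) for r in reports])
    return AggregateReport(
        reports=reports,
        mean_accuracy=float(acc.mean()),
        std_accuracy=float(acc.std(ddof=1)) if acc.size > 1 else 0.0,
        mean_confusion=np.mean([r.confusion for r in reports], axis=0),
        mean_loss_curve=np.nanmean(loss, axis=0),
        mean_val_curve=np.nanmean(val, axis=0),
        classes=reports[0].classes,
    )


class SpectralCNN:
    """CNN classifier of cell types from 2D spectral maps.

    Parameters
    ----------
    spectra : sequence of Spectrum2D
        The (possibly augmented) cohort; class labels and parent ids are
        read from the spectra.
    arch : AnnArchitecture
        Network variant and training hyperparameters.
    split : SplitSpec
        Celltype-aware partition fractions.
    crop : bool
        Crop to the cell-peak window before rasterizing (recommended for
        the MSC task; the cell-line task also works full-frame).
    """

    def __init__(
        self,
        spectra: Sequence[Spectrum2D],
        arch: Optional[AnnArchitecture] = None,
        split: Optional[SplitSpec] = None,
        crop: bool = True,
    ):
        self.spectra = list(spectra)
        self.arch = arch or AnnArchitecture()
        self.split = split or SplitSpec()
        self.crop = crop
        self._images = spectra_to_images(self.spectra, self.arch.input_size, crop=crop)

    def fit(self, seed: int = 0, n_replicates: int = 1):
        """Train; returns a :class:`TrainingReport` for one replicate or an
        :class:`AggregateReport` for several."""
        if n_replicates == 1:
            return train_ann(
                self.spectra, self.arch, self.split, seed=seed, crop=self.crop,
                images=self._images,
            )
        return replicate_runs(
            lambda s, i: train_ann(
                self.spectra, self.arch, self.split, seed=s, crop=self.crop,
                replicate_index=i, images=self._images,
            ),
            n_replicates=n_replicates,
            seed=seed,
        )


# ---------------------------------------------------------------------------
# combination search
# ---------------------------------------------------------------------------


def combination_search(
    records: Sequence[CentroidRecord],
    k: int,
    config: Optional[SvmConfig] = None,
    n_replicates: int = 10,
    scorer: Optional[Callable[[Sequence[CentroidRecord], int], float]] = None,
) -> pd.DataFrame:
    """Score every k-class subset by mean replicate accuracy.

    Default scorer is the replicated centroid SVM; pass ``scorer`` to rank
    subsets under a different classifier.  Returns a table sorted by mean
    accuracy descending (ties broken lexicographically by class names).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    classes = sorted({str(r.class_label) for r in records})
    if k > len(classes):
        raise ValueError(f"k={k} exceeds number of classes {len(classes)}")
    config = config or SvmConfig()
    rows = []
    for combo in itertools.combinations(classes, k):
        subset = [r for r in records if str(r.class_label) in combo]
        if scorer is None:
            cfg = SvmConfig(**{**config.__dict__, "replicates": n_replicates})
            _, stats = run_svm_replicates(subset, cfg)
            mean = stats["mean"]
        else:
            mean = float(np.mean([scorer(subset, rep) for rep in range(n_replicates)]))
        rows.append({"classes": ", ".join(combo), "k": k, "mean_accuracy": mean})
    table = pd.DataFrame(rows).sort_values(
        ["mean_accuracy", "classes"], ascending=[False, True], ignore_index=True
    )
    return table
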