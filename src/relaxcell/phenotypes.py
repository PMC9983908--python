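"""Relaxation phenotypes: the generative model of a cell sample.

A sample is modelled as a mixture of relaxation components, each a single
(T1, T2) site with an amplitude (its share of the equilibrium magnetization)
and a per-replicate log-normal positional jitter.  Cell suspensions carry a
short-relaxation "cell peak" plus a long-relaxation "media peak" from the
excess culture medium; adipogenically differentiated MSCs gain an additional
lipid peak.

The numeric (T1, T2) positions of the ten cell lines and the MSC stages are
package defaults chosen to emulate the observed cluster layout, not measured
ground truth; all are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List

import numpy as np
import pandas as pd

__all__ = [
    "RelaxationComponent",
    "RelaxationPhenotype",
    "CohortManifest",
    "make_adcp_phantom",
    "default_phenotype_library",
    "reference_cohort_manifest",
    "CELL_LINE_REPLICATE_COUNTS",
]


@dataclass(frozen=True)
class RelaxationComponent:
    """One (T1, T2) site of a mixture.

    ``jitter_log_t1`` / ``jitter_log_t2`` are standard deviations in log10
    seconds of the per-replicate positional scatter.
    """

    t1: float
    t2: float
    amplitude: float = 1.0
    jitter_log_t1: float = 0.0
    jitter_log_t2: float = 0.0

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("t1 and t2 must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.jitter_log_t1 < 0 or self.jitter_log_t2 < 0:
            raise ValueError("jitters must be >= 0")


@dataclass(frozen=True)
class RelaxationPhenotype:
    """Named mixture of relaxation components."""

    name: str
    components: tuple

    def __init__(self, name: str, components: Iterable[RelaxationComponent]):
        comps = tuple(components)
        if not comps:
            raise ValueError("phenotype needs at least one component")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "components", comps)

    def scaled(self, k: float) -> "RelaxationPhenotype":
        """Scale every component amplitude by ``k``."""
        return RelaxationPhenotype(
            self.name,
            [
                RelaxationComponent(c.t1, c.t2, c.amplitude * k, c.jitter_log_t1, c.jitter_log_t2)
                for c in self.components
            ],
        )


def make_adcp_phantom(
    t1: float = 0.55,
    t2: float = 0.065,
    amplitude: float = 1.0,
    jitter_log: float = 0.01,
) -> RelaxationPhenotype:
    """Agarose-Dotagraf cell phantom: a single relaxation site tuned to mimic
    a CHO-like cell peak.

    The contrast agent sets T2 and the agarose fraction sets T1, so the
    phantom shows a single stable peak, unlike real cell samples which carry
    a media peak as well.
    """
    return RelaxationPhenotype(
        "ADCP",
        [RelaxationComponent(t1, t2, amplitude, jitter_log, jitter_log)],
    )


# Default media peak: long T1 from the mostly-free water of the culture
# medium.  Kept at T2 <= T1 (a T2 exceeding T1 is not physical for these
# samples).
_MEDIA = dict(t1=2.5, t2=1.6, amplitude=0.6, jitter_log_t1=0.02, jitter_log_t2=0.03)

# Cell-peak defaults: stand-in positions spread over T1 in [0.3, 1.5] s and
# T2 in [0.02, 0.3] s, emulating the distinct per-line clusters.
_CELL_PEAKS: Dict[str, tuple] = {
    # name: (t1, t2)
    "A549": (0.55, 0.055),
    "C2C12": (0.75, 0.090),
    "CHO": (0.45, 0.035),
    "HEK293T": (0.95, 0.130),
    "HeLa": (0.62, 0.170),
    "K562": (1.25, 0.060),
    "L929": (0.35, 0.110),
    "MDA231": (1.05, 0.230),
    "THP1": (0.85, 0.042),
    "Vero": (1.45, 0.150),
}

# Per-replicate positional scatter of cell peaks, calibrated so synthetic
# centroid clouds show the measured behaviour: elongation along T2 and
# substantial overlap between neighbouring lines.
_CELL_JITTER = dict(jitter_log_t1=0.06, jitter_log_t2=0.10)


def default_phenotype_library() -> Dict[str, RelaxationPhenotype]:
    """Phenotype library emulating the measured dataset: ten cell lines,
    undifferentiated and adipogenically differentiated MSCs, the ADCP
    phantom, and a media-only control."""
    lib: Dict[str, RelaxationPhenotype] = {}
    for name, (t1, t2) in _CELL_PEAKS.items():
        lib[name] = RelaxationPhenotype(
            name,
            [
                RelaxationComponent(t1, t2, amplitude=1.0, **_CELL_JITTER),
                RelaxationComponent(**_MEDIA),
            ],
        )
    # Undifferentiated MSC: single cell peak + media.
    lib["MSC_undiff"] = RelaxationPhenotype(
        "MSC_undiff",
        [
            RelaxationComponent(0.70, 0.080, amplitude=1.0, **_CELL_JITTER),
            RelaxationComponent(**_MEDIA),
        ],
    )
    # Differentiated MSC: the water cell peak plus a lipid peak at shorter
    # T1 and longer T2 (triglyceride protons), plus media.
    lib["MSC_diff"] = RelaxationPhenotype(
        "MSC_diff",
        [
            RelaxationComponent(0.70, 0.080, amplitude=0.7, **_CELL_JITTER),
            RelaxationComponent(0.28, 0.19, amplitude=0.5, **_CELL_JITTER),
            RelaxationComponent(**_MEDIA),
        ],
    )
    lib["ADCP"] = make_adcp_phantom()
    lib["media_only"] = RelaxationPhenotype(
        "media_only", [RelaxationComponent(**_MEDIA)]
    )
    return lib


@dataclass
class CohortManifest:
    """Table of samples to simulate: one row per biological sample group.

    ``rows`` is a DataFrame with columns
    ``sample_id, phenotype, class_label, n_replicates, seed``.
    """

    rows: pd.DataFrame

    REQUIRED = ("sample_id", "phenotype", "class_label", "n_replicates", "seed")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.rows.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        if self.rows["sample_id"].duplicated().any():
            raise ValueError("sample_ids must be unique")
        if (self.rows["n_replicates"] < 1).any():
            raise ValueError("n_replicates must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(self.rows["n_replicates"].sum())

    @classmethod
    def from_counts(
        cls, counts: Dict[str, int], seed: int = 0, class_labels: Dict[str, str] | None = None
    ) -> "CohortManifest":
        """Build a manifest with one row per phenotype from a count mapping."""
        class_labels = class_labels or {}
        rows = pd.DataFrame(
            {
                "sample_id": list(counts),
                "phenotype": list(counts),
                "class_label": [class_labels.get(k, k) for k in counts],
                "n_replicates": list(counts.values()),
                "seed": seed,
            }
        )
        return cls(rows)

    @classmethod
    def read_csv(cls, path) -> "CohortManifest":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def library_to_yaml(library: Dict[str, RelaxationPhenotype], path) -> None:
    """Write a phenotype library as a YAML config (one entry per phenotype,
    one mapping per component)."""
    import yaml

    payload = {
        name: [
            {
                "t1": c.t1, "t2": c.t2, "amplitude": c.amplitude,
                "jitter_log_t1": c.jitter_log_t1, "jitter_log_t2": c.jitter_log_t2,
            }
            for c in ph.components
        ]
        for name, ph in library.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def library_from_yaml(path) -> Dict[str, RelaxationPhenotype]:
    """Read a phenotype library written by :func:`library_to_yaml`."""
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return {
        name: RelaxationPhenotype(name, [RelaxationComponent(**comp) for comp in comps])
        for name, comps in payload.items()
    }


#: Per-line biological replicate counts of the study this generator
#: emulates.  The study's per-line tally sums to 339 while its stated total
#: implies 354 cell-line replicates; the 15-sample shortfall is not
#: attributable to any particular line, so both manifest variants exist.
CELL_LINE_REPLICATE_COUNTS: Dict[str, int] = {
    "A549": 17,
    "C2C12": 30,
    "CHO": 61,
    "HEK293T": 21,
    "HeLa": 24,
    "K562": 57,
    "L929": 30,
    "MDA231": 57,
    "THP1": 26,
    "Vero": 16,
}

_MSC_COUNTS = {"MSC_undiff": 8, "MSC_diff": 7}


def reference_cohort_manifest(
    variant: str = "full", include_msc: bool = True, seed: int = 0
) -> CohortManifest:
    """Manifest emulating the measured dataset composition.

    variant "tabulated": the per-line counts exactly as tallied (339
    cell-line samples).  variant "full": padded round-robin to the stated
    354 cell-line replicates, so the cohort with both MSC stages totals
    369 samples.  The padding is a stand-in for the 15 replicates the two
    tallies disagree about.
    """
    counts = dict(CELL_LINE_REPLICATE_COUNTS)
    if variant == "full":
        names = sorted(counts, key=lambda k: -counts[k])
        for i in range(354 - sum(counts.values())):
            counts[names[i % len(names)]] += 1
    elif variant != "tabulated":
        raise ValueError(f"unknown manifest variant {variant!r}")
    if include_msc:
        counts.update(_MSC_COUNTS)
    return CohortManifest.from_counts(counts, seed=seed)
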