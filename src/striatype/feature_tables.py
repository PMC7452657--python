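"""Class-conditional sampler of intrinsic-property tables.

Generates labeled 12-feature tables (one row per cell) for benchmarking the
clustering and classification stages without recordings.  Each class is an
independent Gaussian in feature space; the shipped benchmark preset encodes
three phenotypes (MSN / THIN / FAN) whose means differ by at least three
pooled standard deviations along at least three features for every class
pair, so a competent classifier separates them.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .ephys import FEATURE_NAMES
from .exceptions import SpecError

__all__ = ["ClassSpec", "sample_feature_table", "benchmark_specs", "CLASS_LABELS"]

#: Fixed class order used for reproducible tie-breaks everywhere.
CLASS_LABELS = ("MSN", "THIN", "FAN")


@dataclass(frozen=True)
class ClassSpec:
    """Gaussian feature distribution for one cell class."""

    class_label: str
    feature_means: tuple[float, ...]
    feature_sds: tuple[float, ...]
    n_cells: int = 50

    def __post_init__(self) -> None:
        means = tuple(float(m) for m in self.feature_means)
        sds = tuple(float(s) for s in self.feature_sds)
        object.__setattr__(self, "feature_means", means)
        object.__setattr__(self, "feature_sds", sds)
        if len(means) != len(FEATURE_NAMES) or len(sds) != len(FEATURE_NAMES):
            raise SpecError(
                f"feature_means and feature_sds must have length {len(FEATURE_NAMES)}"
            )
        if any(s <= 0 for s in sds):
            raise SpecError("feature_sds must all be positive")
        if self.n_cells < 1:
            raise SpecError("n_cells must be >= 1")


def sample_feature_table(specs: list[ClassSpec], seed: int = 0) -> pd.DataFrame:
    """Draw a labeled feature table: one row per cell, 12 feature columns
    named as in :data:`~striatype.ephys.FEATURE_NAMES` plus a ``label``
    column.  Reproducible under ``seed``.
    """
    if len(specs) < 1:
        raise SpecError("need at least one class spec")
    rng = np.random.default_rng(seed)
    blocks = []
    for spec in specs:
        x = rng.normal(
            np.array(spec.feature_means),
            np.array(spec.feature_sds),
            size=(spec.n_cells, len(FEATURE_NAMES)),
        )
        df = pd.DataFrame(x, columns=list(FEATURE_NAMES))
        df["label"] = spec.class_label
        blocks.append(df)
    out = pd.concat(blocks, ignore_index=True)
    out.index.name = "cell_id"
    return out


def benchmark_specs(n_cells: int = 50) -> list[ClassSpec]:
    """The shipped three-class benchmark (MSN / THIN / FAN phenotypes)."""
    text = (
        importlib.resources.files("striatype") / "presets" / "benchmark.yaml"
    ).read_text()
    raw = yaml.safe_load(text)
    specs = []
    for label in CLASS_LABELS:
        entry = raw[label]
        specs.append(
            ClassSpec(
                class_label=label,
                feature_means=tuple(entry["means"]),
                feature_sds=tuple(entry["sds"]),
                n_cells=n_cells,
            )
        )
    return specs
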