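"""Synthetic TPM expression matrices with planted grade-specific markers.

The generator emulates the structure the pipeline consumes: a samples ×
features TPM matrix with log-normal background expression, a configurable
per-class imbalance (default 10/55/24/10/4, the Gleason-group sizes of the
motivating cohort), a small disjoint set of marker features per class whose
log2 expression is shifted upward by ``effect_size`` within that class,
and random dropout zeros. Marker placement depends only on the seed, so a
matched held-out partition can be drawn from the same ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gradepanel.data_model import ExpressionMatrix, LabelVector
from gradepanel.seeding import derive_seed

# canonical score string per group, for writing 5-class label files
_CANONICAL_SCORE = {1: "6", 2: "3+4=7", 3: "4+3=7", 4: "8", 5: "9"}


@dataclass
class SimulationConfig:
    class_sizes: list[int] = field(default_factory=lambda: [10, 55, 24, 10, 4])
    n_features: int = 2000
    markers_per_class: int = 3
    effect_size: float = 2.0
    base_log_mean: float = 3.0
    base_log_sd: float = 1.5
    dropout_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_sizes) < 2:
            raise ValueError("need at least two classes")
        if any(s < 1 for s in self.class_sizes):
            raise ValueError("every class needs at least one sample")
        if self.n_features < len(self.class_sizes) * self.markers_per_class:
            raise ValueError("not enough features to place disjoint marker sets")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.markers_per_class < 1:
            raise ValueError("markers_per_class must be >= 1")


@dataclass
class SimulatedDataset:
    matrix: ExpressionMatrix
    labels: LabelVector
    truth: dict[int, list[str]]     # class -> planted marker feature IDs
    effect_size: float

    def truth_table(self) -> pd.DataFrame:
        rows = [
            {"class": c, "feature_id": f, "effect_size": self.effect_size}
            for c in sorted(self.truth)
            for f in self.truth[c]
        ]
        return pd.DataFrame(rows, columns=["class", "feature_id", "effect_size"])


def _feature_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"T{j:0{width}d}" for j in range(n)]


def simulate(config: SimulationConfig, partition: str = "train") -> SimulatedDataset:
    """Draw one dataset partition from the configured ground truth.

    Marker placement is derived from the seed alone, so ``train`` and
    ``test`` partitions of the same config share the same planted markers
    while their sample values are independent. Background log2 expression
    is Normal(base_log_mean, base_log_sd); a class's markers get
    ``effect_size`` added to their in-class log2 mean; TPM is 2**log2;
    dropout independently zeroes entries.
    """
    classes = list(range(1, len(config.class_sizes) + 1))
    n = int(sum(config.class_sizes))
    p = config.n_features
    feature_ids = _feature_ids(p)

    marker_rng = np.random.default_rng(derive_seed(config.seed, "markers"))
    chosen = marker_rng.choice(p, size=len(classes) * config.markers_per_class, replace=False)
    truth = {
        c: sorted(feature_ids[j] for j in chosen[i * config.markers_per_class:(i + 1) * config.markers_per_class])
        for i, c in enumerate(classes)
    }

    rng = np.random.default_rng(derive_seed(config.seed, f"samples:{partition}"))
    groups = np.repeat(classes, config.class_sizes)
    log2_expr = rng.normal(config.base_log_mean, config.base_log_sd, size=(n, p))
    fid_col = {f: j for j, f in enumerate(feature_ids)}
    for c in classes:
        cols = [fid_col[f] for f in truth[c]]
        rows = np.flatnonzero(groups == c)
        log2_expr[np.ix_(rows, cols)] += config.effect_size
    tpm = np.exp2(log2_expr)
    if config.dropout_rate > 0:
        tpm[rng.random(size=(n, p)) < config.dropout_rate] = 0.0

    sample_ids = [f"{partition}_S{i:04d}" for i in range(n)]
    raw_scores = None
    if set(classes) <= set(_CANONICAL_SCORE):
        raw_scores = [_CANONICAL_SCORE[int(g)] for g in groups]
    matrix = ExpressionMatrix(sample_ids=sample_ids, feature_ids=feature_ids, values=tpm)
    labels = LabelVector(sample_ids=sample_ids, groups=groups, raw_scores=raw_scores)
    return SimulatedDataset(matrix=matrix, labels=labels, truth=truth, effect_size=config.effect_size)


def truth_recovery_report(
    selected_features_per_class: dict[int, list[str]],
    dataset: SimulatedDataset,
) -> pd.DataFrame:
    """Precision/recall of planted-marker recovery per class.

    ``selected_features_per_class`` maps each class to the features chosen
    by the node that isolates it. Unknown feature or class IDs are
    rejected rather than scored as misses.
    """
    known = set(dataset.matrix.feature_ids)
    rows = []
    for c, selected in sorted(selected_features_per_class.items()):
        if c not in dataset.truth:
            raise KeyError(f"class {c} has no planted truth")
        unknown = [f for f in selected if f not in known]
        if unknown:
            raise KeyError(f"unknown feature IDs for class {c}: {unknown}")
        sel = set(selected)
        tru = set(dataset.truth[c])
        hits = len(sel & tru)
        rows.append(
            {
                "class": c,
                "n_selected": len(sel),
                "n_truth": len(tru),
                "n_recovered": hits,
                "precision": hits / len(sel) if sel else 0.0,
                "recall": hits / len(tru) if tru else 0.0,
            }
        )
    return pd.DataFrame(
        rows, columns=["class", "n_selected", "n_truth", "n_recovered", "precision", "recall"]
    )
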