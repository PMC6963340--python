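"""Core data types, Gleason score→group mapping, and file I/O.

Expression data are held internally as a samples × features matrix of TPM
(transcripts-per-million) values. On disk the conventional orientation is
GCT-style: rows = features (transcripts/genes), columns = samples, with a
header row of sample IDs and the first column holding feature IDs. The
orientation is never guessed — a flag states which way a file is written.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

SCHEMA_VERSION = 1

# Epstein's five-level consolidation of Gleason scores. Scores 2-5 are no
# longer assigned in modern practice and are rejected.
_GLEASON_GROUPS = {
    "6": 1,
    "3+4=7": 2,
    "3+4": 2,
    "4+3=7": 3,
    "4+3": 3,
    "8": 4,
    "9": 5,
    "10": 5,
}


def map_gleason_score_to_group(raw_score: str) -> int:
    """Map a Gleason score string to its group (1-5).

    Recognised forms: "6", "3+4=7", "4+3=7", "8", "9", "10" (whitespace
    insensitive; the "=7" suffix may be omitted). Already-consolidated
    labels are accepted as "group1".."group9" — a distinct vocabulary, so
    obsolete numeric scores like "2" are still rejected.
    """
    if not isinstance(raw_score, str):
        raise TypeError(f"Gleason score must be a string, got {type(raw_score).__name__}")
    normalised = re.sub(r"\s+", "", raw_score)
    m = re.fullmatch(r"group([1-9])", normalised, flags=re.IGNORECASE)
    if m:
        return int(m.group(1))
    try:
        return _GLEASON_GROUPS[normalised]
    except KeyError:
        raise ValueError(
            f"Unrecognised Gleason score {raw_score!r}: expected one of "
            "'6', '3+4=7', '4+3=7', '8', '9', '10' (scores 2-5 are no longer assigned)"
        ) from None


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups = [i for i in ids if i in seen or seen.add(i)]
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class ExpressionMatrix:
    """Samples × features TPM matrix with aligned identifiers.

    Invariants: values finite and non-negative, IDs unique, shape matches
    the ID lists. ``values[i, j]`` is the abundance of feature ``j`` in
    sample ``i``.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"expression values must be 2-D, got shape {self.values.shape}")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.sample_ids)} samples × {len(self.feature_ids)} features"
            )
        _check_unique(self.sample_ids, "sample IDs")
        _check_unique(self.feature_ids, "feature IDs")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at sample {self.sample_ids[bad[0]]!r}, "
                f"feature {self.feature_ids[bad[1]]!r}"
            )
        if np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative TPM value at sample {self.sample_ids[bad[0]]!r}, "
                f"feature {self.feature_ids[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def log2p1(self) -> np.ndarray:
        """log2(TPM + 1), the default transform for downstream modelling."""
        return np.log2(self.values + 1.0)

    def subset_features(self, feature_ids: Sequence[str]) -> np.ndarray:
        """Column-select named features, erroring on any absent one."""
        index = {f: j for j, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in index]
        if missing:
            raise KeyError(f"features absent from matrix: {missing}")
        cols = [index[f] for f in feature_ids]
        return self.values[:, cols]


def read_expression_matrix(
    path, orientation: str = "features_by_samples"
) -> ExpressionMatrix:
    """Read a delimited TPM matrix (TSV or CSV, sniffed from the suffix).

    ``orientation`` names the FILE layout: ``"features_by_samples"``
    (GCT-style body: rows = features, header = sample IDs; the default) or
    ``"samples_by_features"``. The in-memory object is always samples ×
    features.
    """
    if orientation not in ("features_by_samples", "samples_by_features"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty expression matrix in {path}")
    try:
        numeric = df.astype(float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().argmax()]
                raise ValueError(
                    f"non-numeric cell at row {row!r}, column {col!r} in {path}"
                ) from None
        raise
    if numeric.isna().to_numpy().any():
        pos = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at row {numeric.index[pos[0]]!r}, "
            f"column {numeric.columns[pos[1]]!r} in {path}"
        )
    if orientation == "features_by_samples":
        feature_ids = list(numeric.index)
        sample_ids = list(numeric.columns)
        values = numeric.to_numpy().T
    else:
        sample_ids = list(numeric.index)
        feature_ids = list(numeric.columns)
        values = numeric.to_numpy()
    return ExpressionMatrix(sample_ids=sample_ids, feature_ids=feature_ids, values=values)


def write_expression_matrix(
    matrix: ExpressionMatrix, path, orientation: str = "features_by_samples"
) -> None:
    """Write a TPM matrix in the stated file orientation."""
    if orientation not in ("features_by_samples", "samples_by_features"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = "," if str(path).endswith(".csv") else "\t"
    if orientation == "features_by_samples":
        df = pd.DataFrame(
            matrix.values.T, index=matrix.feature_ids, columns=matrix.sample_ids
        )
        df.index.name = "feature_id"
    else:
        df = pd.DataFrame(
            matrix.values, index=matrix.sample_ids, columns=matrix.feature_ids
        )
        df.index.name = "sample_id"
    df.to_csv(path, sep=sep)


@dataclass
class LabelVector:
    """Per-sample grade-group assignments, ID-aligned with a matrix."""

    sample_ids: list[str]
    groups: np.ndarray
    raw_scores: list[str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.groups = np.asarray(self.groups, dtype=int)
        if self.groups.ndim != 1 or len(self.groups) != len(self.sample_ids):
            raise ValueError("groups must be a vector aligned with sample_ids")
        _check_unique(self.sample_ids, "sample IDs")

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def classes(self) -> list[int]:
        return sorted(set(int(g) for g in self.groups))

    def aligned_to(self, matrix: ExpressionMatrix) -> "LabelVector":
        """Reorder to the matrix's sample order, erroring on any mismatch."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in matrix.sample_ids if s not in pos]
        extra = [s for s in self.sample_ids if s not in set(matrix.sample_ids)]
        if missing or extra:
            parts = []
            if missing:
                parts.append(f"samples without labels: {missing}")
            if extra:
                parts.append(f"labelled samples absent from matrix: {extra}")
            raise ValueError("label/matrix mismatch — " + "; ".join(parts))
        order = [pos[s] for s in matrix.sample_ids]
        return LabelVector(
            sample_ids=list(matrix.sample_ids),
            groups=self.groups[order],
            raw_scores=None if self.raw_scores is None else [self.raw_scores[i] for i in order],
        )


def read_labels(path) -> LabelVector:
    """Read a two-column delimited file: sample_id, Gleason score string."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment=None)
    # tolerate a header line if the second field is not a recognisable score
    first = df.iloc[0] if len(df) else None
    if first is not None:
        try:
            map_gleason_score_to_group(str(first[1]))
        except (ValueError, TypeError, KeyError):
            df = df.iloc[1:]
    if len(df) == 0:
        raise ValueError(f"empty label file: {path}")
    if df.shape[1] < 2:
        raise ValueError(f"label file must have two columns (sample_id, score): {path}")
    sample_ids = [str(s) for s in df.iloc[:, 0]]
    raw_scores = [str(s) for s in df.iloc[:, 1]]
    groups = [map_gleason_score_to_group(s) for s in raw_scores]
    return LabelVector(sample_ids=sample_ids, groups=np.array(groups), raw_scores=raw_scores)


def write_labels(labels: LabelVector, path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    scores = labels.raw_scores or [f"group{int(g)}" for g in labels.groups]
    pd.DataFrame({"sample_id": labels.sample_ids, "score": scores}).to_csv(
        path, sep=sep, header=False, index=False
    )


@dataclass
class HierarchyNode:
    """One decision point: a binary classifier isolating ``target_class``.

    One-vs-rest nodes leave ``other_class`` as None; the final two-class
    node names both sides explicitly.
    """

    target_class: int
    selected_feature_ids: list[str]
    classifier_kind: str
    classifier_parameters: dict
    node_metrics: dict | None = None
    other_class: int | None = None

    def to_dict(self) -> dict:
        return {
            "target_class": int(self.target_class),
            "selected_feature_ids": list(self.selected_feature_ids),
            "classifier_kind": self.classifier_kind,
            "classifier_parameters": self.classifier_parameters,
            "node_metrics": self.node_metrics,
            "other_class": None if self.other_class is None else int(self.other_class),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HierarchyNode":
        return cls(
            target_class=int(d["target_class"]),
            selected_feature_ids=list(d["selected_feature_ids"]),
            classifier_kind=str(d["classifier_kind"]),
            classifier_parameters=dict(d["classifier_parameters"]),
            node_metrics=d.get("node_metrics"),
            other_class=None if d.get("other_class") is None else int(d["other_class"]),
        )


@dataclass
class HierarchyModel:
    """Ordered list of decision points plus the class isolation order.

    For C input classes there are exactly C−1 decision points: C−2
    one-vs-rest nodes followed by one final two-class node.
    """

    nodes: list[HierarchyNode]
    class_order: list[int]
    log_transform: bool = True
    training_feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        c = len(self.class_order)
        if c < 2:
            raise ValueError("a hierarchy needs at least two classes")
        if len(self.nodes) != c - 1:
            raise ValueError(
                f"{c} classes require {c - 1} decision points, got {len(self.nodes)}"
            )
        if len(set(self.class_order)) != c:
            raise ValueError("class_order contains duplicates")
        if self.nodes[-1].other_class is None:
            raise ValueError("final node must be a two-class node")
        if self.training_feature_ids:
            known = set(self.training_feature_ids)
            for node in self.nodes:
                unknown = [f for f in node.selected_feature_ids if f not in known]
                if unknown:
                    raise ValueError(
                        f"node for class {node.target_class} selects features "
                        f"absent from training: {unknown}"
                    )

    @property
    def required_features(self) -> list[str]:
        seen: dict[str, None] = {}
        for node in self.nodes:
            for f in node.selected_feature_ids:
                seen.setdefault(f, None)
        return list(seen)

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "class_order": [int(c) for c in self.class_order],
            "log_transform": bool(self.log_transform),
            "training_feature_ids": list(self.training_feature_ids),
            "nodes": [n.to_dict() for n in self.nodes],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HierarchyModel":
        version = d.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported model schema version {version!r} (expected {SCHEMA_VERSION})"
            )
        return cls(
            nodes=[HierarchyNode.from_dict(n) for n in d["nodes"]],
            class_order=[int(c) for c in d["class_order"]],
            log_transform=bool(d.get("log_transform", True)),
            training_feature_ids=list(d.get("training_feature_ids", [])),
        )


def serialize_model(model: HierarchyModel, path) -> None:
    """Write a model as a schema-versioned JSON document."""
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_model(path) -> HierarchyModel:
    """Load a serialized model, rejecting corrupted or mismatched files."""
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupted model file {path}: {exc}") from exc
    if not isinstance(payload, dict):
        raise ValueError(f"corrupted model file {path}: not a JSON object")
    return HierarchyModel.from_dict(payload)
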