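"""Greedy construction of the one-vs-rest classification hierarchy.

The multiclass problem is decomposed into a chain of binary decisions: at
each internal node every remaining class is evaluated as positive-vs-rest
under stratified cross-validation (with class rebalancing and hybrid
feature selection re-run inside each training fold), and the class whose
classifier scores the highest accuracy is isolated — removing its samples
before recursing. Isolating the easiest class first limits how far an
early mistake can propagate down the chain. The last two classes are
separated by a direct binary node.

Per node, Gaussian naive Bayes and a linear-kernel SVM are compared on the
same folds; the better-by-accuracy kind is kept and refitted on all
remaining samples once the class is fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from gradepanel.classifiers import CLASSIFIER_KINDS, NodeClassifier
from gradepanel.data_model import ExpressionMatrix, HierarchyModel, HierarchyNode, LabelVector
from gradepanel.evaluation import (
    ConfusionCounts,
    NodeMetrics,
    confusion,
    metrics_from_confusion,
    stratified_folds,
)
from gradepanel.feature_selection import SelectionConfig, mrmr_wrapper_select
from gradepanel.resampling import ResamplingConfig, ncl_clean, rebalance
from gradepanel.seeding import derive_seed


@dataclass
class HierarchyBuildConfig:
    cv_folds: int = 10
    classifier_kinds: tuple[str, ...] = CLASSIFIER_KINDS
    resampling: ResamplingConfig = field(default_factory=ResamplingConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    min_class_size: int = 4
    log_transform: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not self.classifier_kinds:
            raise ValueError("need at least one classifier kind")
        for k in self.classifier_kinds:
            if k not in CLASSIFIER_KINDS:
                raise ValueError(f"unknown classifier kind {k!r}")


@dataclass
class NodeCandidateEvaluation:
    """Cross-validated scorecard for isolating one candidate class."""

    candidate_class: int
    metrics: NodeMetrics
    classifier_kind: str
    selected_features: list[str]
    metrics_by_kind: dict[str, NodeMetrics] = field(default_factory=dict)
    fold_records: list[dict] = field(default_factory=list)


@dataclass
class BuildResult:
    model: HierarchyModel
    trace: list[dict] = field(default_factory=list)
    evaluations: list[NodeCandidateEvaluation] = field(default_factory=list)

    def trace_table(self):
        import pandas as pd

        return pd.DataFrame(self.trace)


def make_one_vs_rest_labels(y, positive_class: int) -> np.ndarray:
    """Binary labels: 1 for the positive class, 0 for the pooled rest."""
    y = np.asarray(y, dtype=int)
    if positive_class not in set(y.tolist()):
        raise ValueError(f"class {positive_class} absent from labels")
    y_bin = (y == positive_class).astype(int)
    if y_bin.all():
        raise ValueError(f"all samples belong to class {positive_class}; no rest to contrast")
    return y_bin


def _fit_and_select(
    X: np.ndarray,
    y_bin: np.ndarray,
    feature_ids: list[str],
    config: HierarchyBuildConfig,
    seed_role: str,
) -> tuple[list[str], np.ndarray, np.ndarray, list[dict]]:
    """Rebalance then select features on a training set.

    NCL cleaning runs first on the full feature space; the hybrid filter +
    wrapper selection then sees only surviving *original* samples (synthetic
    interpolations carry no independent evidence, so letting them into the
    entropy statistics would overstate noise features); finally SMOTE
    balances the selected-feature training matrix for classifier fitting.

    Returns (selected feature IDs, rebalanced X restricted to them,
    rebalanced labels, provenance records with row indices into ``X``).
    """
    rcfg = replace(config.resampling, seed=derive_seed(config.seed, seed_role + ":resample"))
    scfg = replace(config.selection, seed=derive_seed(config.seed, seed_role + ":select"))
    sel = mrmr_wrapper_select(X, y_bin, feature_ids, scfg)
    col = {f: j for j, f in enumerate(feature_ids)}
    cols = [col[f] for f in sel.selected_feature_ids]
    kept = ncl_clean(X[:, cols], y_bin, rcfg)
    resampled = rebalance(X[kept][:, cols], y_bin[kept], rcfg, apply_ncl=False)
    provenance = []
    for rec in resampled.provenance:
        provenance.append(
            {
                "origin": rec["origin"],
                "parents": tuple(int(kept[p]) for p in rec["parents"]),
                **({"u": rec["u"]} if "u" in rec else {}),
            }
        )
    return sel.selected_feature_ids, resampled.X, resampled.y, provenance


def evaluate_candidate(
    X: np.ndarray,
    y: np.ndarray,
    candidate_class: int,
    feature_ids: list[str],
    config: HierarchyBuildConfig,
) -> NodeCandidateEvaluation:
    """Score one class as positive-vs-rest under stratified outer CV.

    Rebalancing and feature selection run on each training fold only; the
    evaluation fold is predicted untouched. Confusion counts are pooled
    across folds per classifier kind and the best kind by accuracy is
    retained (ties defer to the configured kind order).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    y_bin = make_one_vs_rest_labels(y, candidate_class)
    fold_seed = derive_seed(config.seed, f"folds:{candidate_class}")
    folds = stratified_folds(y_bin, config.cv_folds, fold_seed)

    counts = {k: ConfusionCounts(0, 0, 0, 0) for k in config.classifier_kinds}
    truths: dict[str, list[np.ndarray]] = {k: [] for k in config.classifier_kinds}
    scores: dict[str, list[np.ndarray]] = {k: [] for k in config.classifier_kinds}
    fold_records: list[dict] = []
    selected_union: dict[str, None] = {}

    for i, (tr, te) in enumerate(folds):
        role = f"cand{candidate_class}:fold{i}"
        sel_ids, X_res, y_res, provenance = _fit_and_select(
            X[tr], y_bin[tr], feature_ids, config, role
        )
        for f in sel_ids:
            selected_union.setdefault(f, None)
        col = {f: j for j, f in enumerate(feature_ids)}
        test_cols = [col[f] for f in sel_ids]
        X_te = X[te][:, test_cols]
        for kind in config.classifier_kinds:
            clf = NodeClassifier.fit(kind, X_res, y_res)
            s = clf.decision_scores(X_te)
            pred = (s > 0.0).astype(int)
            counts[kind] = counts[kind] + confusion(y_bin[te], pred)
            truths[kind].append(y_bin[te])
            scores[kind].append(s)
        # provenance parents are positions within the training fold; map to
        # absolute row indices so leakage can be audited post hoc
        abs_prov = []
        for rec in provenance:
            abs_prov.append(
                {
                    "origin": rec["origin"],
                    "parents": tuple(int(tr[p]) for p in rec["parents"]),
                    **({"u": rec["u"]} if "u" in rec else {}),
                }
            )
        fold_records.append(
            {
                "fold": i,
                "train_idx": np.asarray(tr),
                "test_idx": np.asarray(te),
                "selected_features": sel_ids,
                "provenance": abs_prov,
            }
        )

    metrics_by_kind = {
        k: metrics_from_confusion(
            counts[k], np.concatenate(truths[k]), np.concatenate(scores[k])
        )
        for k in config.classifier_kinds
    }
    best_kind = max(
        config.classifier_kinds,
        key=lambda k: (
            metrics_by_kind[k].accuracy,
            -config.classifier_kinds.index(k),
        ),
    )
    return NodeCandidateEvaluation(
        candidate_class=int(candidate_class),
        metrics=metrics_by_kind[best_kind],
        classifier_kind=best_kind,
        selected_features=list(selected_union),
        metrics_by_kind=metrics_by_kind,
        fold_records=fold_records,
    )


def _candidate_sort_key(ev: NodeCandidateEvaluation):
    # highest accuracy, then sensitivity, then specificity, then lowest class
    m = ev.metrics
    return (-m.accuracy, -m.sensitivity, -m.specificity, ev.candidate_class)


def _refit_node(
    X: np.ndarray,
    y_bin: np.ndarray,
    feature_ids: list[str],
    kind: str,
    config: HierarchyBuildConfig,
    seed_role: str,
) -> tuple[list[str], NodeClassifier]:
    sel_ids, X_res, y_res, _ = _fit_and_select(X, y_bin, feature_ids, config, seed_role)
    clf = NodeClassifier.fit(kind, X_res, y_res)
    return sel_ids, clf


def build_hierarchy(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: list[str],
    config: HierarchyBuildConfig | None = None,
) -> BuildResult:
    """Build the greedy one-vs-rest hierarchy over all classes in ``y``.

    While more than two classes remain, every eligible class is evaluated
    one-vs-rest and the highest-accuracy class is fixed as the next node
    (ties: sensitivity, then specificity, then lower label — the candidate
    measures in their reporting order); its samples are then removed. The
    final two classes share a direct binary node. Ultra-small classes (at
    most ``min_class_size`` samples) are held back from early isolation
    when any larger class is available, mirroring the practice of deciding
    very small groups at the last split.

    Returns a :class:`BuildResult` whose ``model`` is serializable and
    whose ``trace`` records every candidate evaluation at every level.
    """
    if config is None:
        config = HierarchyBuildConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    feature_ids = [str(f) for f in feature_ids]
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least two classes to build a hierarchy")

    active = np.arange(len(y))
    remaining = list(classes)
    nodes: list[HierarchyNode] = []
    class_order: list[int] = []
    trace: list[dict] = []
    evaluations: list[NodeCandidateEvaluation] = []
    level = 0

    def record(level: int, ev: NodeCandidateEvaluation, chosen: bool) -> None:
        m = ev.metrics
        trace.append(
            {
                "level": level,
                "candidate_class": ev.candidate_class,
                "classifier_kind": ev.classifier_kind,
                "Accuracy": m.accuracy,
                "Sensitivity": m.sensitivity,
                "Specificity": m.specificity,
                "F-Measure": m.f_measure,
                "MCC": m.mcc,
                "ROC Area": m.roc_area,
                "chosen": chosen,
                "selected_features": ";".join(ev.selected_features),
            }
        )

    while len(remaining) > 2:
        level += 1
        counts = {c: int((y[active] == c).sum()) for c in remaining}
        eligible = [c for c in remaining if counts[c] > config.min_class_size]
        if not eligible:
            eligible = list(remaining)
        evals = []
        for c in eligible:
            try:
                evals.append(
                    evaluate_candidate(X[active], y[active], c, feature_ids, config)
                )
            except ValueError as exc:  # e.g. stratification impossible
                import warnings

                warnings.warn(f"candidate class {c} skipped at level {level}: {exc}")
        if not evals:
            raise RuntimeError(f"no candidate class could be evaluated at level {level}")
        evals.sort(key=_candidate_sort_key)
        best = evals[0]
        for ev in evals:
            record(level, ev, ev is best)
            evaluations.append(ev)

        y_bin = make_one_vs_rest_labels(y[active], best.candidate_class)
        sel_ids, clf = _refit_node(
            X[active], y_bin, feature_ids, best.classifier_kind, config,
            f"refit:level{level}:class{best.candidate_class}",
        )
        nodes.append(
            HierarchyNode(
                target_class=best.candidate_class,
                selected_feature_ids=sel_ids,
                classifier_kind=best.classifier_kind,
                classifier_parameters=clf.parameters,
                node_metrics=best.metrics.as_report_row(),
            )
        )
        class_order.append(best.candidate_class)
        active = active[y[active] != best.candidate_class]
        remaining.remove(best.candidate_class)

    # final direct two-class node: evaluate both orientations, keep the better
    level += 1
    final_evals = []
    for c in remaining:
        try:
            final_evals.append(
                evaluate_candidate(X[active], y[active], c, feature_ids, config)
            )
        except ValueError:
            pass
    if not final_evals:
        raise RuntimeError("final two-class node could not be evaluated")
    final_evals.sort(key=_candidate_sort_key)
    best = final_evals[0]
    for ev in final_evals:
        record(level, ev, ev is best)
        evaluations.append(ev)
    other = [c for c in remaining if c != best.candidate_class][0]
    y_bin = make_one_vs_rest_labels(y[active], best.candidate_class)
    sel_ids, clf = _refit_node(
        X[active], y_bin, feature_ids, best.classifier_kind, config,
        f"refit:final:class{best.candidate_class}",
    )
    nodes.append(
        HierarchyNode(
            target_class=best.candidate_class,
            selected_feature_ids=sel_ids,
            classifier_kind=best.classifier_kind,
            classifier_parameters=clf.parameters,
            node_metrics=best.metrics.as_report_row(),
            other_class=other,
        )
    )
    class_order.extend([best.candidate_class, other])

    model = HierarchyModel(
        nodes=nodes,
        class_order=class_order,
        log_transform=config.log_transform,
        training_feature_ids=feature_ids,
    )
    return BuildResult(model=model, trace=trace, evaluations=evaluations)


def predict(model: HierarchyModel, matrix, feature_ids: list[str] | None = None) -> np.ndarray:
    """Assign one class per sample by walking the hierarchy.

    Samples traverse the nodes in isolation order; the first node whose
    classifier fires positive assigns its target class, and samples
    reaching the final node take its binary decision. ``matrix`` may be an
    :class:`ExpressionMatrix` (raw TPM; the model's stored transform is
    applied) or a plain array accompanied by ``feature_ids`` in the same
    (already transformed) space the model was trained on.
    """
    if isinstance(matrix, ExpressionMatrix):
        values = matrix.log2p1() if model.log_transform else matrix.values
        ids = matrix.feature_ids
    else:
        if feature_ids is None:
            raise ValueError("feature_ids required when predicting from a plain array")
        values = np.asarray(matrix, dtype=float)
        ids = [str(f) for f in feature_ids]
    col = {f: j for j, f in enumerate(ids)}
    n = values.shape[0]
    out = np.full(n, -1, dtype=int)
    undecided = np.ones(n, dtype=bool)
    for node in model.nodes:
        missing = [f for f in node.selected_feature_ids if f not in col]
        if missing:
            raise KeyError(
                f"features {missing} required by the node for class "
                f"{node.target_class} are absent from the input matrix"
            )
        cols = [col[f] for f in node.selected_feature_ids]
        clf = NodeClassifier(node.classifier_kind, node.classifier_parameters)
        idx = np.flatnonzero(undecided)
        if idx.size == 0:
            break
        pred = clf.predict(values[idx][:, cols])
        if node.other_class is None:
            hit = idx[pred == 1]
            out[hit] = node.target_class
            undecided[hit] = False
        else:
            out[idx[pred == 1]] = node.target_class
            out[idx[pred == 0]] = node.other_class
            undecided[idx] = False
    return out


def evaluate_model(model: HierarchyModel, matrix: ExpressionMatrix, labels: LabelVector):
    """Per-node and overall performance of a trained hierarchy on labelled data.

    Each node is scored as the binary problem it was trained for, over the
    samples still in play at its level (true class among the not-yet-
    isolated classes). Returns (per-node rows, overall accuracy percent,
    predictions).
    """
    from gradepanel.evaluation import overall_accuracy, roc_area

    aligned = labels.aligned_to(matrix)
    y = np.asarray(aligned.groups, dtype=int)
    if matrix.n_samples == 0:
        raise ValueError("empty matrix")
    values = matrix.log2p1() if model.log_transform else matrix.values
    col = {f: j for j, f in enumerate(matrix.feature_ids)}
    rows = []
    remaining = list(model.class_order)
    for node in model.nodes:
        missing = [f for f in node.selected_feature_ids if f not in col]
        if missing:
            raise KeyError(
                f"features {missing} required by the node for class "
                f"{node.target_class} are absent from the input matrix"
            )
        in_play = np.isin(y, remaining)
        if not in_play.any():
            continue
        cols = [col[f] for f in node.selected_feature_ids]
        clf = NodeClassifier(node.classifier_kind, node.classifier_parameters)
        scores = clf.decision_scores(values[in_play][:, cols])
        pred = (scores > 0.0).astype(int)
        y_bin = (y[in_play] == node.target_class).astype(int)
        counts = confusion(y_bin, pred)
        try:
            auc = roc_area(y_bin, scores)
        except ValueError:
            auc = None
        m = metrics_from_confusion(counts)
        m.roc_area = auc
        label = (
            f"{node.target_class} vs. Rest"
            if node.other_class is None
            else f"{node.target_class} vs. {node.other_class}"
        )
        rows.append({"node": label, **m.as_report_row()})
        remaining.remove(node.target_class)
    preds = predict(model, matrix)
    overall = overall_accuracy(int((preds == y).sum()), len(y))
    return rows, overall, preds


def train_model(
    matrix: ExpressionMatrix,
    labels: LabelVector,
    config: HierarchyBuildConfig | None = None,
) -> BuildResult:
    """Convenience front door: align labels, transform, build."""
    if config is None:
        config = HierarchyBuildConfig()
    aligned = labels.aligned_to(matrix)
    values = matrix.log2p1() if config.log_transform else matrix.values
    return build_hierarchy(values, aligned.groups, matrix.feature_ids, config)
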