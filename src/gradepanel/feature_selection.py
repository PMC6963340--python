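"""Hybrid two-stage feature selection for a binary one-vs-rest problem.

Stage 1 is an information-gain (IG) filter: every feature is discretised
(equal-frequency bins by default, edges learned on training data only) and
ranked by IG(A, X) = H(A) − H(A|X), the reduction in class entropy from
conditioning on the binned feature. The top ``top_k`` survive.

Stage 2 is a minimum-redundancy–maximum-relevance (mRMR) wrapper: features
are grown greedily, preferring candidates that maximise

    V − W,   V = (1/|S|)  Σ_{i∈S} I(h, i),   W = (1/|S|²) Σ_{i,j∈S} I(i, j)

(relevance to the class h minus pairwise redundancy; the redundancy double
sum excludes the i = j diagonal by default — including a feature's self-
information H(f) would penalise high-resolution features regardless of how
redundant they actually are, drowning the relevance term; a flag restores
the literal diagonal-inclusive form). A candidate is kept only when it
strictly improves the
stratified inner-CV accuracy of a linear-kernel SVM on the growing subset.

All entropies are in bits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC


# ---------------------------------------------------------------------------
# entropy primitives

def _codes(values) -> np.ndarray:
    return np.unique(np.asarray(values), return_inverse=True)[1]


def entropy(labels) -> float:
    """Shannon entropy of a discrete vector, in bits (0·log 0 := 0)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("entropy of an empty vector is undefined")
    counts = np.bincount(_codes(labels))
    p = counts[counts > 0] / labels.size
    return float(-(p * np.log2(p)).sum())


def conditional_entropy(labels, feature_bins) -> float:
    """H(A | X) = Σ_x p(x) H(A | X = x), in bits; empty bins contribute 0."""
    labels = np.asarray(labels)
    feature_bins = np.asarray(feature_bins)
    if labels.shape != feature_bins.shape:
        raise ValueError(
            f"length mismatch: {labels.shape} labels vs {feature_bins.shape} bins"
        )
    if labels.size == 0:
        raise ValueError("conditional entropy of empty vectors is undefined")
    a = _codes(labels)
    x = _codes(feature_bins)
    n_a, n_x = a.max() + 1, x.max() + 1
    joint = np.bincount(x * n_a + a, minlength=n_a * n_x).reshape(n_x, n_a)
    n = labels.size
    h = 0.0
    px = joint.sum(axis=1) / n
    for i in range(n_x):
        row = joint[i]
        total = row.sum()
        if total == 0:
            continue
        p = row[row > 0] / total
        h += px[i] * -(p * np.log2(p)).sum()
    return float(h)


def mutual_information(u_bins, v_bins) -> float:
    """I(U; V) = H(U) + H(V) − H(U, V), in bits; symmetric, non-negative."""
    u = np.asarray(u_bins)
    v = np.asarray(v_bins)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    uc, vc = _codes(u), _codes(v)
    joint = uc * (vc.max() + 1) + vc
    return max(0.0, entropy(u) + entropy(v) - entropy(joint))


# ---------------------------------------------------------------------------
# discretisation

@dataclass
class DiscretizationScheme:
    """Per-feature binning of continuous expression into ``n_bins`` levels.

    Edges are learned on training data only (``fit``) and reused verbatim
    for held-out data. Equal-frequency edges are quantile-based; duplicate
    quantiles (heavy ties, e.g. dropout zeros) collapse, so a feature may
    end up with fewer than ``n_bins`` occupied levels.
    """

    method: str = "equal_frequency"
    n_bins: int = 10
    min_bin_count: int = 10
    bin_edges: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.method not in ("equal_frequency", "equal_width"):
            raise ValueError(f"unknown discretisation method {self.method!r}")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")

    def effective_bins(self, n_samples: int) -> int:
        """Bin count actually used: ``n_bins`` is a ceiling, lowered so each
        bin expects at least ``min_bin_count`` samples (never below 2).

        Entropy estimates from sparsely occupied bins are strongly biased
        upward, which lets noise features outscore genuine markers on
        small training sets; tying the resolution to n keeps the IG and
        MI statistics comparable across node sizes.
        """
        return int(np.clip(n_samples // self.min_bin_count, 2, self.n_bins))

    def fit(self, X: np.ndarray) -> "DiscretizationScheme":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        edges: list[np.ndarray] = []
        n_bins = self.effective_bins(X.shape[0])
        if self.method == "equal_frequency":
            qs = np.arange(1, n_bins) / n_bins
            cuts = np.quantile(X, qs, axis=0)
            for j in range(X.shape[1]):
                edges.append(np.unique(cuts[:, j]))
        else:
            lo, hi = X.min(axis=0), X.max(axis=0)
            for j in range(X.shape[1]):
                if hi[j] <= lo[j]:
                    edges.append(np.empty(0))
                else:
                    edges.append(np.linspace(lo[j], hi[j], n_bins + 1)[1:-1])
        self.bin_edges = edges
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.bin_edges is None:
            raise RuntimeError("scheme not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.bin_edges):
            raise ValueError(
                f"{X.shape[1]} features but scheme was fitted on {len(self.bin_edges)}"
            )
        out = np.empty(X.shape, dtype=np.int64)
        for j, e in enumerate(self.bin_edges):
            out[:, j] = np.searchsorted(e, X[:, j], side="right")
        return out

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def information_gain(labels, feature_values, scheme: DiscretizationScheme | None = None) -> float:
    """IG of one continuous feature w.r.t. the class vector, in bits."""
    x = np.asarray(feature_values, dtype=float).reshape(-1, 1)
    if scheme is None:
        scheme = DiscretizationScheme()
    if scheme.bin_edges is None:
        bins = scheme.fit_transform(x)
    else:
        bins = scheme.transform(x)
    ig = entropy(labels) - conditional_entropy(labels, bins[:, 0])
    return float(max(ig, 0.0))


# ---------------------------------------------------------------------------
# IG ranking

@dataclass
class IGRanking:
    """Features ordered by descending IG (ties: lexicographic feature ID)."""

    feature_ids: list[str]
    scores: np.ndarray
    h_class: float


def rank_by_ig(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: list[str],
    scheme: DiscretizationScheme | None = None,
    top_k: int | None = None,
) -> IGRanking:
    """Rank every feature by information gain and keep the top ``top_k``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if scheme is None:
        scheme = DiscretizationScheme()
    bins = scheme.fit_transform(X) if scheme.bin_edges is None else scheme.transform(X)
    h_a = entropy(y)
    scores = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        scores[j] = max(h_a - conditional_entropy(y, bins[:, j]), 0.0)
    order = sorted(range(X.shape[1]), key=lambda j: (-scores[j], str(feature_ids[j])))
    if top_k is not None:
        if top_k < 1:
            raise ValueError("top_k must be >= 1")
        if top_k > X.shape[1]:
            warnings.warn(
                f"top_k={top_k} exceeds feature count {X.shape[1]}; full ranking returned",
                stacklevel=2,
            )
        order = order[:top_k]
    return IGRanking(
        feature_ids=[str(feature_ids[j]) for j in order],
        scores=scores[np.array(order)],
        h_class=h_a,
    )


# ---------------------------------------------------------------------------
# mRMR

class MRMRState:
    """Incrementally maintained relevance/redundancy sums over a subset S.

    Caches pairwise feature MI and class-relevance MI so candidate scoring
    is O(|S|) per candidate after warm-up. ``include_diagonal`` keeps the
    i = j terms of the redundancy double sum (W of a singleton is then the
    feature's own entropy).
    """

    def __init__(
        self,
        bins: np.ndarray,
        y: np.ndarray,
        feature_ids: list[str],
        include_diagonal: bool = False,
    ):
        self.bins = np.asarray(bins)
        self.y = np.asarray(y)
        self.feature_ids = list(feature_ids)
        self.include_diagonal = include_diagonal
        self.selected: list[int] = []
        self.relevance_sum = 0.0       # Σ_{i∈S} I(h, i)
        self.redundancy_sum = 0.0      # Σ_{i,j∈S} I(i, j) per the diagonal flag
        self.wrapper_accuracy: float | None = None
        self._mi_class: dict[int, float] = {}
        self._mi_pair: dict[tuple[int, int], float] = {}

    def mi_class(self, j: int) -> float:
        if j not in self._mi_class:
            self._mi_class[j] = mutual_information(self.y, self.bins[:, j])
        return self._mi_class[j]

    def mi_pair(self, i: int, j: int) -> float:
        key = (i, j) if i <= j else (j, i)
        if key not in self._mi_pair:
            self._mi_pair[key] = mutual_information(self.bins[:, key[0]], self.bins[:, key[1]])
        return self._mi_pair[key]

    def _augmented_sums(self, candidate: int) -> tuple[float, float]:
        v = self.relevance_sum + self.mi_class(candidate)
        w = self.redundancy_sum + 2.0 * sum(self.mi_pair(i, candidate) for i in self.selected)
        if self.include_diagonal:
            w += self.mi_pair(candidate, candidate)
        return v, w

    def score(self, candidate: int) -> float:
        """V − W of S ∪ {candidate} (set-mean relevance minus redundancy)."""
        if candidate in self.selected:
            raise ValueError(f"candidate {candidate} already selected")
        v_sum, w_sum = self._augmented_sums(candidate)
        m = len(self.selected) + 1
        return v_sum / m - w_sum / (m * m)

    def vw(self, candidate: int) -> tuple[float, float]:
        v_sum, w_sum = self._augmented_sums(candidate)
        m = len(self.selected) + 1
        return v_sum / m, w_sum / (m * m)

    def add(self, candidate: int) -> None:
        v_sum, w_sum = self._augmented_sums(candidate)
        self.selected.append(candidate)
        self.relevance_sum = v_sum
        self.redundancy_sum = w_sum

    def recompute_sums(self) -> tuple[float, float]:
        """From-scratch Σ relevance and Σ redundancy (consistency check)."""
        v = sum(self.mi_class(i) for i in self.selected)
        w = sum(
            self.mi_pair(i, j)
            for i in self.selected
            for j in self.selected
            if self.include_diagonal or i != j
        )
        return v, w


def mrmr_score(state: MRMRState, candidate: int) -> float:
    """mRMR objective V_{S∪{c}} − W_{S∪{c}} for one candidate feature."""
    return state.score(candidate)


@dataclass
class SelectionConfig:
    top_k: int = 100
    n_bins: int = 10
    discretization: str = "equal_frequency"
    max_features: int = 15
    min_delta: float = 0.0
    inner_cv_folds: int = 5
    inner_cv_repeats: int = 2
    max_trials_per_step: int = 10
    include_diagonal: bool = False
    seed: int = 0


@dataclass
class SelectionResult:
    selected_feature_ids: list[str]
    wrapper_accuracy: float
    ranking: IGRanking
    trace: list[dict] = field(default_factory=list)


def _inner_cv_accuracy(
    X: np.ndarray, y: np.ndarray, folds: int, seed: int, repeats: int = 1
) -> float:
    """Pooled stratified-CV accuracy of a linear-kernel SVM.

    Repeating the CV with reshuffled folds and averaging reduces the
    variance of the acceptance gate, which otherwise lets lucky noise
    features through on small training sets.
    """
    min_class = int(np.bincount(y).min())
    k = max(2, min(folds, min_class))
    if min_class < 2:
        est = SVC(kernel="linear", C=1.0)
        est.fit(X, y)
        return float((est.predict(X) == y).mean())
    correct = 0
    for r in range(max(1, repeats)):
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + r)
        for train_idx, test_idx in splitter.split(X, y):
            est = SVC(kernel="linear", C=1.0)
            est.fit(X[train_idx], y[train_idx])
            correct += int((est.predict(X[test_idx]) == y[test_idx]).sum())
    return correct / (len(y) * max(1, repeats))


def mrmr_wrapper_select(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: list[str],
    config: SelectionConfig | None = None,
    ranking: IGRanking | None = None,
) -> SelectionResult:
    """Greedy forward mRMR selection wrapped around a linear-SVM accuracy gate.

    At each step the remaining IG-filtered candidates are ordered by mRMR
    score and tried in turn (up to ``max_trials_per_step``): the first whose
    subset strictly improves inner-CV accuracy is kept. Selection stops when
    a whole step yields no improvement or ``max_features`` is reached. If no
    candidate is ever accepted, the single top-IG feature is returned.
    """
    if config is None:
        config = SelectionConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    scheme = DiscretizationScheme(method=config.discretization, n_bins=config.n_bins)
    bins = scheme.fit_transform(X)
    if ranking is None:
        ranking = rank_by_ig(
            X, y, feature_ids, scheme=scheme, top_k=min(config.top_k, X.shape[1])
        )
    col = {str(f): j for j, f in enumerate(feature_ids)}
    candidate_cols = [col[f] for f in ranking.feature_ids]
    rank_pos = {c: r for r, c in enumerate(candidate_cols)}

    state = MRMRState(bins, y, list(feature_ids), include_diagonal=config.include_diagonal)
    best_acc = float(np.bincount(y).max() / len(y))  # empty-model baseline
    remaining = list(candidate_cols)
    trace: list[dict] = []
    step = 0
    while remaining and len(state.selected) < config.max_features:
        step += 1
        scored = sorted(
            ((mrmr_score(state, c), c) for c in remaining),
            key=lambda t: (-t[0], rank_pos[t[1]]),
        )
        accepted_this_step = False
        for score_val, c in scored[: config.max_trials_per_step]:
            cols = state.selected + [c]
            acc = _inner_cv_accuracy(X[:, cols], y, config.inner_cv_folds, config.seed, config.inner_cv_repeats)
            v, w = state.vw(c)
            accept = acc > best_acc + config.min_delta
            trace.append(
                {
                    "step": step,
                    "feature_id": str(feature_ids[c]),
                    "mrmr_score": score_val,
                    "V": v,
                    "W": w,
                    "wrapper_accuracy": acc,
                    "accepted": bool(accept),
                }
            )
            if accept:
                state.add(c)
                best_acc = acc
                remaining.remove(c)
                accepted_this_step = True
                break
        if not accepted_this_step:
            break
    if not state.selected:
        top = candidate_cols[0]
        warnings.warn(
            "wrapper accepted no candidate; falling back to the top-IG feature",
            stacklevel=2,
        )
        state.add(top)
        best_acc = _inner_cv_accuracy(X[:, [top]], y, config.inner_cv_folds, config.seed, config.inner_cv_repeats)
    state.wrapper_accuracy = best_acc
    return SelectionResult(
        selected_feature_ids=[str(feature_ids[c]) for c in state.selected],
        wrapper_accuracy=best_acc,
        ranking=ranking,
        trace=trace,
    )
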