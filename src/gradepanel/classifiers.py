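"""Binary node classifiers: Gaussian naive Bayes and linear-kernel SVM.

Both are fitted with scikit-learn, then reduced to their sufficient
parameters (per-class Gaussian moments; primal hyperplane weights) so a
trained hierarchy serializes to plain JSON and predicts bit-identically
after a round trip, without pickling estimator objects.

Scores are oriented so that larger means "positive" (label 1).
"""

from __future__ import annotations

import numpy as np
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

CLASSIFIER_KINDS = ("gaussian_nb", "linear_svm")


class NodeClassifier:
    """A fitted binary classifier with JSON-round-trippable parameters."""

    def __init__(self, kind: str, parameters: dict):
        if kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {kind!r}; expected one of {CLASSIFIER_KINDS}")
        self.kind = kind
        self.parameters = parameters

    @classmethod
    def fit(cls, kind: str, X: np.ndarray, y: np.ndarray) -> "NodeClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if set(np.unique(y)) != {0, 1}:
            raise ValueError("node classifiers require both binary labels 0 and 1 present")
        if kind == "gaussian_nb":
            est = GaussianNB()
            est.fit(X, y)
            order = np.argsort(est.classes_)  # force [0, 1] parameter order
            params = {
                "class_log_prior": np.log(est.class_prior_[order]).tolist(),
                "theta": est.theta_[order].tolist(),
                "var": est.var_[order].tolist(),
            }
        elif kind == "linear_svm":
            est = SVC(kernel="linear", C=1.0)
            est.fit(X, y)
            coef = np.asarray(est.coef_).ravel()
            intercept = float(np.asarray(est.intercept_).ravel()[0])
            # sklearn's decision_function is positive for classes_[1]
            if est.classes_[1] != 1:
                coef, intercept = -coef, -intercept
            params = {"coef": coef.tolist(), "intercept": intercept}
        else:
            raise ValueError(f"unknown classifier kind {kind!r}")
        return cls(kind, params)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Continuous score per row; > 0 predicts the positive class."""
        X = np.asarray(X, dtype=float)
        if self.kind == "gaussian_nb":
            prior = np.asarray(self.parameters["class_log_prior"], dtype=float)
            theta = np.asarray(self.parameters["theta"], dtype=float)
            var = np.asarray(self.parameters["var"], dtype=float)
            jll = np.empty((X.shape[0], 2))
            for c in (0, 1):
                jll[:, c] = prior[c] + np.sum(
                    -0.5 * np.log(2.0 * np.pi * var[c])
                    - 0.5 * (X - theta[c]) ** 2 / var[c],
                    axis=1,
                )
            return jll[:, 1] - jll[:, 0]
        coef = np.asarray(self.parameters["coef"], dtype=float)
        intercept = float(self.parameters["intercept"])
        return X @ coef + intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_scores(X) > 0.0).astype(int)
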