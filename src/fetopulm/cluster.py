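"""Decision boundary, cluster split and displacement-towards-normality (DTN).

A ridge-regularised logistic regression models the probability of the two
growth classes (control vs FGR) on the *baseline* embedding coordinates.
Its decision boundary splits the population into cluster A (the controls'
decision region, signed score > 0, ties included) and cluster B.  For each
subject the baseline -> hyperoxygenation displacement vector in the
embedding is projected onto the boundary's unit normal, oriented towards the
controls' region: that scalar is the displacement towards normality.  DTN is
compared between clusters with a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression

CONTROL_LABEL = "control"


@dataclass
class DisplacementRecord:
    """Per-subject embedding displacement and its DTN component."""

    subject_id: str
    displacement: np.ndarray
    dtn: float
    cluster: str

    def tangential_norm(self) -> float:
        """Component of the displacement within the boundary (Pythagoras)."""
        return math.sqrt(max(float(self.displacement @ self.displacement)
                             - self.dtn ** 2, 0.0))


class ReactivityBoundary(ClassifierMixin, BaseEstimator):
    """Logistic decision boundary on baseline embedding positions.

    Parameters
    ----------
    ridge:
        L2 penalty strength on the logistic weights (sklearn ``C = 1/ridge``).

    Attributes (after :meth:`fit`)
    ------------------------------
    coef_ : unit-free weight vector w, oriented so the mean signed score of
        the control training points is positive (controls' region = positive
        side).
    intercept_ : scalar b.
    normal_ : w / ||w||, the oriented unit normal used for DTN.
    accuracy_ : training accuracy of the two-class fit.
    classes_ : ``["B", "A"]`` ordering of :meth:`predict` outputs is by sign.
    """

    def __init__(self, ridge: float = 1e-3):
        self.ridge = ridge

    def fit(self, X, y):
        """Fit on baseline coordinates ``X`` (N x d) and group labels ``y``
        (strings; ``"control"`` marks the reference class)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be an N x d coordinate matrix")
        classes = set(y.tolist())
        if len(classes) != 2:
            raise ValueError(f"need exactly two classes, got {sorted(classes)}")
        if CONTROL_LABEL not in classes:
            raise ValueError(f"one class must be labelled {CONTROL_LABEL!r}")
        if X.shape[0] <= X.shape[1]:
            raise ValueError("need more observations than embedding dimensions")
        lr = LogisticRegression(C=1.0 / self.ridge, max_iter=2000)
        lr.fit(X, (y == CONTROL_LABEL).astype(int))
        w = lr.coef_[0].astype(float)
        b = float(lr.intercept_[0])
        nw = float(np.linalg.norm(w))
        if nw == 0:
            raise ValueError("degenerate logistic fit: zero weight vector")
        # orientation convention: controls' mean signed score positive
        if np.mean(X[y == CONTROL_LABEL] @ w + b) < 0:
            w, b = -w, -b
        self.coef_ = w
        self.intercept_ = b
        self.normal_ = w / nw
        self.classes_ = np.array(["B", "A"])
        self.accuracy_ = float(np.mean(
            (X @ w + b > 0) == (y == CONTROL_LABEL)))
        self.n_per_class_ = {
            "control": int(np.sum(y == CONTROL_LABEL)),
            "other": int(np.sum(y != CONTROL_LABEL)),
        }
        return self

    def decision_function(self, X) -> np.ndarray:
        """Signed score w.x + b (positive on the controls' side)."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.coef_.size:
            raise ValueError(
                f"dimension mismatch: model is {self.coef_.size}-D, "
                f"coordinates are {X.shape[-1]}-D")
        return X @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        """Cluster labels: ``"A"`` on the controls' side (score >= 0, the
        documented tie-break), ``"B"`` otherwise."""
        return np.where(self.decision_function(X) >= 0, "A", "B")

    def dtn(self, base_coord, mhox_coord) -> float:
        """Displacement towards normality of one subject.

        ``(mhox - base) . w / ||w||`` with the controls-positive orientation;
        invariant under rescaling of w.
        """
        self._check_fitted()
        base = np.asarray(base_coord, dtype=float)
        mhox = np.asarray(mhox_coord, dtype=float)
        if base.shape != mhox.shape or base.size != self.normal_.size:
            raise ValueError("coordinate dimension mismatch with the fitted model")
        return float((mhox - base) @ self.normal_)

    def _check_fitted(self) -> None:
        if not hasattr(self, "coef_"):
            raise RuntimeError("ReactivityBoundary is not fitted")


def fit_boundary(baseline_coords, labels, ridge: float = 1e-3) -> ReactivityBoundary:
    """Functional wrapper over :class:`ReactivityBoundary`."""
    return ReactivityBoundary(ridge=ridge).fit(baseline_coords, labels)


def assign_clusters(baseline_coords, model: ReactivityBoundary) -> np.ndarray:
    """Cluster label per subject from the fitted boundary."""
    return model.predict(baseline_coords)


def compute_dtn(base_coord, mhox_coord, model: ReactivityBoundary) -> float:
    """DTN scalar for one subject (see :meth:`ReactivityBoundary.dtn`)."""
    return model.dtn(base_coord, mhox_coord)


def displacement_records(
    subject_ids, base_coords, mhox_coords, model: ReactivityBoundary,
) -> list:
    """Displacement + DTN + cluster for every subject."""
    base_coords = np.asarray(base_coords, dtype=float)
    mhox_coords = np.asarray(mhox_coords, dtype=float)
    clusters = model.predict(base_coords)
    out = []
    for sid, b, m, c in zip(subject_ids, base_coords, mhox_coords, clusters):
        out.append(DisplacementRecord(
            subject_id=sid, displacement=m - b,
            dtn=model.dtn(b, m), cluster=str(c)))
    return out


def compare_dtn(records: list) -> dict:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney, mid-rank ties) of DTN by
    cluster, with medians and IQRs per cluster."""
    groups = {"A": [], "B": []}
    for r in records:
        if r.cluster not in groups:
            raise ValueError(f"unknown cluster label {r.cluster!r}")
        groups[r.cluster].append(r.dtn)
    for name, vals in groups.items():
        if not vals:
            raise ValueError(f"cluster {name} is empty; comparison undefined")
    a = np.asarray(groups["A"])
    b = np.asarray(groups["B"])
    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                       use_continuity=False)
    summary = {}
    for name, vals in (("A", a), ("B", b)):
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        summary[name] = {"n": int(vals.size), "median": float(med),
                         "iqr": (float(q1), float(q3))}
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "clusters": summary}
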