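"""Subtype prediction from methylation profiles.

The primary classifier is nearest-centroid with median centroids and Spearman
correlation as the similarity: each class is summarised by the per-CpG median
β over its training samples, and a new sample is assigned to the class whose
centroid it rank-correlates with best.  Medians and rank correlation suit β
values, which are bounded and far from Gaussian.  Because Spearman depends
only on ranks, the prediction is invariant under any common strictly
monotone transform of the profiles.

A random forest (off-the-shelf, seeded) serves as a baseline, and a
confusion-matrix helper reports per-class error rates as
misclassified / class size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted


class MedianCentroidClassifier(ClassifierMixin, BaseEstimator):
    """Nearest-centroid classification with median centroids and Spearman
    correlation.

    ``fit(X, y)`` takes samples × CpGs input (β values; NaN allowed) and
    stores one per-class centroid of per-CpG medians.  ``predict`` assigns
    each sample to the class with the highest Spearman correlation between
    the sample profile and the centroid, computed over the sample's
    non-missing CpGs (at least 3 required).  Exact correlation ties go to the
    lexicographically first class; :meth:`predict_detail` exposes the
    per-class correlations, the margin (best − second best) and a tie flag.
    """

    def fit(self, X, y):
        values = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if values.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        self.classes_ = np.array(sorted(pd.unique(y)))
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        else:
            self.feature_names_in_ = np.asarray(
                [str(i) for i in range(values.shape[1])], dtype=object
            )
        self.n_features_in_ = values.shape[1]
        centroids = np.empty((len(self.classes_), values.shape[1]))
        for i, c in enumerate(self.classes_):
            sub = values[y == c]
            if sub.shape[0] == 0:
                raise ValueError(f"class {c!r} has no training samples")
            centroids[i] = np.nanmedian(sub, axis=0)
        self.centroids_ = pd.DataFrame(
            centroids, index=self.classes_, columns=self.feature_names_in_
        )
        return self

    def _sample_ids(self, X, n):
        if isinstance(X, pd.DataFrame):
            return list(X.index)
        return list(range(n))

    def decision_function(self, X):
        """Spearman correlation of each sample against each class centroid."""
        check_is_fitted(self, "centroids_")
        if isinstance(X, pd.DataFrame):
            X = X.reindex(columns=self.feature_names_in_)
        values = np.asarray(X, dtype=float)
        ids = self._sample_ids(X, values.shape[0])
        cent = self.centroids_.to_numpy()
        rho = np.empty((values.shape[0], len(self.classes_)))
        for i in range(values.shape[0]):
            x = values[i]
            mask = ~np.isnan(x)
            mask &= ~np.isnan(cent).any(axis=0)
            if mask.sum() < 3:
                raise ValueError(
                    f"sample {ids[i]!r}: fewer than 3 usable CpGs for rank correlation"
                )
            if np.nanstd(x[mask]) == 0:
                raise ValueError(
                    f"sample {ids[i]!r}: zero-variance profile, correlation undefined"
                )
            for k in range(len(self.classes_)):
                rho[i, k] = stats.spearmanr(x[mask], cent[k, mask]).statistic
        return rho

    def predict(self, X):
        rho = self.decision_function(X)
        # NaN correlations (constant centroid on the usable CpGs) lose
        filled = np.where(np.isnan(rho), -np.inf, rho)
        return self.classes_[np.argmax(filled, axis=1)]

    def predict_detail(self, X) -> pd.DataFrame:
        """Per-sample table: predicted class, per-class rho, margin, tie flag."""
        rho = self.decision_function(X)
        ids = self._sample_ids(X, rho.shape[0])
        filled = np.where(np.isnan(rho), -np.inf, rho)
        best = np.argmax(filled, axis=1)
        out = pd.DataFrame(
            rho, index=pd.Index(ids, name="sample_id"),
            columns=[f"rho_{c}" for c in self.classes_],
        )
        out["predicted"] = self.classes_[best]
        if len(self.classes_) > 1:
            sorted_rho = np.sort(filled, axis=1)
            margin = sorted_rho[:, -1] - sorted_rho[:, -2]
            out["margin"] = np.where(np.isfinite(margin), margin, np.nan)
            out["tied"] = margin == 0
        else:
            out["margin"] = np.nan
            out["tied"] = False
        return out


@dataclass
class ConfusionResult:
    """Confusion matrix with per-class error rates.

    ``error_rates`` keeps full precision; ``error_rates_display`` rounds to
    2 decimals for tabulation.
    """

    counts: pd.DataFrame       # true class × predicted class
    error_rates: pd.Series
    error_rates_display: pd.Series

    @property
    def overall_error(self) -> float:
        total = self.counts.to_numpy().sum()
        correct = np.diag(self.counts.to_numpy()).sum()
        return 1.0 - correct / total


def build_centroids(
    train: pd.DataFrame, labels: pd.Series, cpg_set=None
) -> MedianCentroidClassifier:
    """Fit a :class:`MedianCentroidClassifier` from a file-layout β matrix
    (CpGs × samples), optionally restricted to ``cpg_set``."""
    if cpg_set is not None:
        missing = [c for c in cpg_set if c not in train.index]
        if missing:
            raise ValueError(f"CpGs absent from training matrix: {missing[:5]}")
        if len(cpg_set) == 0:
            raise ValueError("empty CpG set")
        train = train.loc[list(cpg_set)]
    labels = pd.Series(labels).reindex(train.columns)
    return MedianCentroidClassifier().fit(train.T, labels.to_numpy())


def predict_nearest_centroid(
    profiles: pd.DataFrame, model: MedianCentroidClassifier
) -> pd.DataFrame:
    """Predict subtypes for a file-layout β matrix (CpGs × samples)."""
    return model.predict_detail(profiles.T)


def random_forest_predict(
    train: pd.DataFrame,
    labels: pd.Series,
    test: pd.DataFrame,
    cpg_set=None,
    n_trees: int = 500,
    seed: int = 0,
) -> pd.Series:
    """Random-forest baseline on file-layout matrices; seeded and therefore
    reproducible.  Vote ties resolve to the lexicographically first class."""
    if cpg_set is not None:
        train = train.loc[list(cpg_set)]
        test = test.loc[list(cpg_set)]
    else:
        test = test.loc[train.index]
    labels = pd.Series(labels).reindex(train.columns)
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    rf.fit(train.T.to_numpy(), labels.to_numpy())
    pred = rf.predict(test.T.to_numpy())
    return pd.Series(pred, index=test.columns, name="predicted")


def confusion_and_error(
    true_labels: pd.Series, predictions: pd.Series, classes=None
) -> ConfusionResult:
    """Confusion matrix and per-class error = misclassified / class size."""
    t = pd.Series(true_labels)
    p = pd.Series(predictions)
    p = p.reindex(t.index)
    if p.isna().any():
        raise ValueError("predictions missing for some samples")
    if classes is None:
        classes = sorted(set(t) | set(p))
    else:
        stray = (set(t) | set(p)) - set(classes)
        if stray:
            raise ValueError(f"labels outside the class set: {sorted(stray)}")
    counts = (
        pd.crosstab(t, p)
        .reindex(index=classes, columns=classes, fill_value=0)
        .rename_axis(index="true", columns="predicted")
    )
    row_tot = counts.sum(axis=1)
    diag = pd.Series(np.diag(counts.to_numpy()), index=counts.index)
    with np.errstate(invalid="ignore"):
        err = (row_tot - diag) / row_tot
    return ConfusionResult(
        counts=counts,
        error_rates=err,
        error_rates_display=err.round(2),
    )
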