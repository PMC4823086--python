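"""CpG selection strategies preceding high-level analysis.

Three filters are provided, each as a scikit-learn feature selector
(``fit``/``transform`` on samples × CpGs input) and as a module-level
function on the file-layout matrix (CpGs × samples):

* top-variance — the k most variable CpGs across samples.  Beware: β-value
  variance is maximal for hemi-methylated CpGs, so this filter tends to
  select hemi-methylated sites rather than biologically interesting ones.
* differential vs normal — a CpG passes if its β departs from the normal-mean
  by more than ``delta`` (default 0.2, i.e. 20 percentage points of
  methylation) in at least ``min_frac`` (default 30%) of tumor samples.
* test-based — CpGs significant in the Kruskal–Wallis scan at a FWER bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from . import compare

DIRECTIONS = ("both", "hyper", "hypo")


@dataclass
class FilterResult:
    """Outcome of a CpG filter: the selected ids, the rule that produced
    them, and the per-CpG score used for ranking."""

    selected: list
    criterion: dict = field(default_factory=dict)
    scores: pd.Series | None = None


def _feature_names(X, n_features):
    if isinstance(X, pd.DataFrame):
        return np.asarray(X.columns, dtype=object)
    return np.asarray([str(i) for i in range(n_features)], dtype=object)


class VarianceSelector(SelectorMixin, BaseEstimator):
    """Keep the ``k`` features with largest across-sample variance.

    Variance uses the n−1 denominator over non-missing values; exact-variance
    ties are broken by feature name in lexicographic order.
    """

    def __init__(self, k: int = 100):
        self.k = k

    def fit(self, X, y=None):
        values = np.asarray(X, dtype=float)
        n_features = values.shape[1]
        if not 1 <= self.k <= n_features:
            raise ValueError(f"k={self.k} out of range [1, {n_features}]")
        names = _feature_names(X, n_features)
        var = np.nanvar(values, axis=0, ddof=1)
        order = np.lexsort((names, -var))
        mask = np.zeros(n_features, dtype=bool)
        mask[order[: self.k]] = True
        self.feature_names_in_ = names
        self.n_features_in_ = n_features
        self.variances_ = var
        self.support_mask_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_mask_")
        return self.support_mask_


class DifferentialSelector(SelectorMixin, BaseEstimator):
    """Select CpGs differentially methylated in tumors vs the normal mean.

    A CpG passes when the fraction of tumor samples whose β differs from the
    per-CpG mean over normal samples by more than ``delta`` (absolute for
    ``direction="both"``, signed for "hyper"/"hypo") is at least
    ``min_frac``.  ``y`` gives sample labels; ``normal_label`` marks the
    reference samples.
    """

    def __init__(
        self,
        delta: float = 0.2,
        min_frac: float = 0.3,
        direction: str = "both",
        normal_label: str = "Normal",
    ):
        self.delta = delta
        self.min_frac = min_frac
        self.direction = direction
        self.normal_label = normal_label

    def fit(self, X, y):
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        values = np.asarray(X, dtype=float)
        y = np.asarray(y)
        normal = y == self.normal_label
        if not normal.any():
            raise ValueError(f"no samples labelled {self.normal_label!r}")
        tumor = ~normal
        if not tumor.any():
            raise ValueError("no tumor samples")
        normal_mean = np.nanmean(values[normal], axis=0)
        diff = values[tumor] - normal_mean
        if self.direction == "both":
            exceeds = np.abs(diff) > self.delta
        elif self.direction == "hyper":
            exceeds = diff > self.delta
        else:
            exceeds = diff < -self.delta
        n_obs = np.sum(~np.isnan(diff), axis=0)
        with np.errstate(invalid="ignore"):
            frac = np.where(n_obs > 0, np.nansum(exceeds, axis=0) / n_obs, 0.0)
        self.feature_names_in_ = _feature_names(X, values.shape[1])
        self.n_features_in_ = values.shape[1]
        self.fractions_ = frac
        self.normal_mean_ = normal_mean
        self.support_mask_ = frac >= self.min_frac
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_mask_")
        return self.support_mask_


class KruskalWallisSelector(SelectorMixin, BaseEstimator):
    """Select CpGs whose Kruskal–Wallis adjusted p falls below a FWER bound.

    ``y`` gives sample group labels; ``groups`` optionally restricts the
    comparison to a subset (e.g. the four tumor subtypes).
    """

    def __init__(self, fwer: float = 0.01, method: str = "holm", groups=None):
        self.fwer = fwer
        self.method = method
        self.groups = groups

    def fit(self, X, y):
        values = np.asarray(X, dtype=float)
        names = _feature_names(X, values.shape[1])
        index = (
            X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(values))
        )
        matrix = pd.DataFrame(values.T, index=names, columns=index)
        labels = pd.Series(np.asarray(y), index=index)
        if labels.nunique() < 2 and (self.groups is None or len(self.groups) < 2):
            raise ValueError("need at least two groups")
        results, selected = compare.differential_cpgs(
            matrix, labels, fwer=self.fwer, groups=self.groups, method=self.method
        )
        results = results.reindex(names)
        self.feature_names_in_ = names
        self.n_features_in_ = values.shape[1]
        self.statistic_ = results["statistic"].to_numpy()
        self.pvalues_ = results["p_value"].to_numpy()
        self.pvalues_adjusted_ = results["p_adjusted"].to_numpy()
        self.support_mask_ = np.isin(names, selected)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_mask_")
        return self.support_mask_


# ---------------------------------------------------------------------------
# module-level functions on file-layout matrices (CpGs × samples)


def top_variance_filter(matrix: pd.DataFrame, k: int) -> FilterResult:
    """The ``k`` CpGs with largest across-sample variance."""
    sel = VarianceSelector(k=k).fit(matrix.T)
    scores = pd.Series(sel.variances_, index=matrix.index, name="variance")
    selected = list(matrix.index[sel.support_mask_])
    selected.sort(key=lambda c: (-scores[c], c))
    return FilterResult(
        selected=selected,
        criterion={"rule": "top_variance", "k": k},
        scores=scores,
    )


def differential_filter(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    delta: float = 0.2,
    min_frac: float = 0.3,
    direction: str = "both",
) -> FilterResult:
    """CpGs whose β differs from the normal mean by > delta in ≥ min_frac of
    tumor samples.  ``tumor`` and ``normal`` must share CpG ids."""
    if normal.shape[1] == 0:
        raise ValueError("need at least one normal sample")
    if not tumor.index.equals(normal.index):
        common = tumor.index.intersection(normal.index)
        if common.empty:
            raise ValueError("tumor and normal matrices share no CpGs")
        tumor, normal = tumor.loc[common], normal.loc[common]
    X = pd.concat([tumor, normal], axis=1).T
    y = np.array(["Tumor"] * tumor.shape[1] + ["Normal"] * normal.shape[1])
    sel = DifferentialSelector(
        delta=delta, min_frac=min_frac, direction=direction
    ).fit(X, y)
    scores = pd.Series(sel.fractions_, index=tumor.index, name="fraction_exceeding")
    return FilterResult(
        selected=list(tumor.index[sel.support_mask_]),
        criterion={
            "rule": "differential_vs_normal",
            "delta": delta,
            "min_frac": min_frac,
            "direction": direction,
        },
        scores=scores,
    )


def rank_by_test(
    matrix: pd.DataFrame,
    labels: pd.Series,
    fwer_threshold: float = 0.01,
    groups=None,
    method: str = "holm",
) -> FilterResult:
    """CpGs significant in the Kruskal–Wallis scan, ranked by adjusted p."""
    labels = pd.Series(labels)
    if labels.reindex(matrix.columns).nunique() < 2:
        raise ValueError("need at least two groups")
    results, selected = compare.differential_cpgs(
        matrix, labels, fwer=fwer_threshold, groups=groups, method=method
    )
    return FilterResult(
        selected=selected,
        criterion={
            "rule": "kruskal_wallis_fwer",
            "fwer": fwer_threshold,
            "method": method,
            "groups": list(groups) if groups is not None else None,
        },
        scores=results["p_adjusted"],
    )
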