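"""Unsupervised class discovery for β-valued methylation profiles.

Two routes, mirroring standard practice for methylation arrays:

* **Hierarchical clustering** of samples with correlation distance
  (d = 1 − Pearson r) and complete linkage, with cluster stability assessed
  by resampling CpGs (features) with replacement: the bootstrap probability
  (BP) of a node is the fraction of replicate trees containing exactly the
  same sample set.  An approximately-unbiased (AU) p-value is available via
  the two-term multiscale-bootstrap regression (z_r = Φ⁻¹(1 − BP_r) fitted
  on (√r, 1/√r); AU = 1 − Φ(v − c)); BP is the supported default.

* **Recursively partitioned beta mixtures** — model-based clustering in
  which each component models every CpG as an independent beta distribution.
  At each node a one-component and a two-component model are fitted by EM
  (responsibilities in the log domain; per-CpG shape updates by weighted
  moment matching), and the node splits when the two-component BIC is lower;
  samples are hard-assigned by maximum responsibility and the recursion
  continues.  The leaves are the methylation classes, so the procedure picks
  the number of clusters itself.

The moment-matching M-step is not an exact maximiser, so each EM iteration
is accepted only if the observed-data log-likelihood does not decrease; the
recorded log-likelihood history is therefore non-decreasing up to ``tol``.
Two-component fits are initialised deterministically from the sign of the
leading principal direction of the centred data, which makes the whole
recursion reproducible and invariant to CpG order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.special import betaln, logsumexp
from sklearn.base import BaseEstimator, ClusterMixin

EPS = 1e-6
SHAPE_FLOOR = 0.01

# ---------------------------------------------------------------------------
# hierarchical clustering with bootstrap support


@dataclass
class Dendrogram:
    """A complete-linkage tree over samples (scipy linkage encoding)."""

    linkage: np.ndarray
    labels: list

    def node_sets(self) -> list[frozenset]:
        """Sample-id sets of all internal nodes, in merge order."""
        n = len(self.labels)
        sets: list[frozenset] = []
        members = {i: frozenset([self.labels[i]]) for i in range(n)}
        for k, (i, j, _, _) in enumerate(self.linkage):
            merged = members[int(i)] | members[int(j)]
            members[n + k] = merged
            sets.append(merged)
        return sets

    def cut(self, k: int) -> pd.Series:
        """Cluster labels (1..k) from cutting the tree into k groups."""
        assign = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(assign, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist) + ";"


def correlation_distance_hclust(beta: pd.DataFrame) -> Dendrogram:
    """Cluster samples (columns) by complete linkage on 1 − Pearson r.

    Columns are processed in sorted sample-id order, which fixes the
    tie-break for equal-distance merges.  A sample with zero variance over
    the CpG set has undefined correlation and raises.
    """
    beta = beta[sorted(beta.columns)]
    X = beta.to_numpy(dtype=float).T  # samples × CpGs
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = beta.columns[int(np.argmax(sd == 0))]
        raise ValueError(f"sample {bad!r} has zero variance over the CpG set")
    d = 1.0 - np.corrcoef(X)
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    Z = hierarchy.linkage(squareform(d, checks=False), method="complete")
    return Dendrogram(linkage=Z, labels=list(beta.columns))


#: scale factors for the multiscale bootstrap
AU_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 2))


def bootstrap_support(
    beta: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    compute_au: bool = False,
) -> tuple[Dendrogram, pd.DataFrame]:
    """Feature-bootstrap support for the sample dendrogram.

    Resamples CpGs (rows) with replacement ``B`` times, reclusters the
    samples, and scores each internal node of the reference tree by the
    fraction of replicates whose tree contains the identical sample set.
    With ``compute_au`` the resampling is repeated at the multiscale factors
    r ∈ {0.5, ..., 1.4} (replicate size ⌈r·n_cpgs⌉) and the AU p-value is
    obtained from the signed-distance regression.

    Returns the reference dendrogram and a per-node table with columns
    ``samples`` (sorted tuple), ``size``, ``bp`` and optionally ``au``.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    rng = np.random.default_rng(seed)
    ref = correlation_distance_hclust(beta)
    ref_sets = ref.node_sets()
    n_cpgs = beta.shape[0]
    scales = AU_SCALES if compute_au else (1.0,)

    bp_by_scale = {}
    for r in scales:
        size = max(3, int(np.ceil(r * n_cpgs)))
        hits = {s: 0 for s in ref_sets}
        for _ in range(B):
            idx = rng.integers(0, n_cpgs, size=size)
            rep = correlation_distance_hclust(beta.iloc[idx])
            rep_sets = set(rep.node_sets())
            for s in ref_sets:
                if s in rep_sets:
                    hits[s] += 1
        bp_by_scale[r] = {s: hits[s] / B for s in ref_sets}

    rows = []
    for s in ref_sets:
        row = {
            "samples": tuple(sorted(s)),
            "size": len(s),
            "bp": bp_by_scale[1.0][s] if 1.0 in bp_by_scale else bp_by_scale[scales[-1]][s],
        }
        if compute_au:
            bps = np.array([bp_by_scale[r][s] for r in scales])
            informative = (bps > 0) & (bps < 1)
            if informative.sum() < 2:
                # BP at floor/ceiling on (almost) every scale: the signed
                # distance is unidentifiable and the plain BP is the answer
                row["au"] = float(np.round(bps.mean()))
            else:
                z = stats.norm.ppf(1.0 - bps[informative])
                sq = np.sqrt(np.asarray(scales)[informative])
                design = np.column_stack([sq, 1.0 / sq])
                (v, c), *_ = np.linalg.lstsq(design, z, rcond=None)
                row["au"] = float(1.0 - stats.norm.cdf(v - c))
        rows.append(row)
    support = pd.DataFrame(rows)
    support.index.name = "node"
    return ref, support


# ---------------------------------------------------------------------------
# beta-mixture EM and recursive partitioning


@dataclass
class BetaMixtureFit:
    """A k-component per-CpG beta mixture fitted to one sample set."""

    weights: np.ndarray          # (k,)
    a: np.ndarray                # (k, n_cpgs)
    b: np.ndarray                # (k, n_cpgs)
    resp: np.ndarray             # (n_samples, k)
    log_likelihood: float
    history: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True

    @property
    def k(self) -> int:
        return len(self.weights)

    def n_params(self) -> int:
        return self.k * 2 * self.a.shape[1] + (self.k - 1)

    def bic(self, n_samples: int) -> float:
        return -2.0 * self.log_likelihood + self.n_params() * np.log(n_samples)


def _moment_match(X: np.ndarray, w: np.ndarray):
    """Weighted method-of-moments beta shapes per CpG.

    Degenerate variances are floored (v → max(v, 1e-6)) and shapes floored at
    0.01, so constant data still yields finite parameters.
    """
    wsum = w.sum()
    m = (w[:, None] * X).sum(axis=0) / wsum
    v = (w[:, None] * (X - m) ** 2).sum(axis=0) / wsum
    v = np.maximum(v, 1e-6)
    m = np.clip(m, EPS, 1 - EPS)
    common = m * (1 - m) / v - 1.0
    a = np.maximum(m * common, SHAPE_FLOOR)
    b = np.maximum((1 - m) * common, SHAPE_FLOOR)
    return a, b


def _log_density(X_log: np.ndarray, X1_log: np.ndarray, a, b) -> np.ndarray:
    """Per-sample log density under each component (n × k)."""
    return (
        X_log @ (a - 1.0).T + X1_log @ (b - 1.0).T - betaln(a, b).sum(axis=1)
    )


def fit_beta_mixture(
    values: np.ndarray,
    k: int = 1,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> BetaMixtureFit:
    """Fit a k ∈ {1, 2} component beta mixture by EM.

    ``values`` is samples × CpGs in [0, 1] (clamped to [1e-6, 1 − 1e-6]);
    within a component CpGs are independent beta variables.  The M-step
    matches weighted moments per CpG; an iteration is only accepted if the
    observed-data log-likelihood does not decrease, so the returned history
    is monotone non-decreasing up to ``tol``.
    """
    X = np.clip(np.asarray(values, dtype=float), EPS, 1 - EPS)
    n, J = X.shape
    if n < 2:
        raise ValueError("need at least two samples")
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    X_log = np.log(X)
    X1_log = np.log1p(-X)

    if k == 1:
        w = np.ones(n)
        a, b = _moment_match(X, w)
        a, b = a[None, :], b[None, :]
        ll = float(_log_density(X_log, X1_log, a, b).sum())
        return BetaMixtureFit(
            weights=np.array([1.0]), a=a, b=b,
            resp=np.ones((n, 1)), log_likelihood=ll, history=[ll], n_iter=1,
        )

    # deterministic init: sign of the leading principal direction
    Xc = X - X.mean(axis=0)
    u = np.linalg.svd(Xc, full_matrices=False)[0][:, 0]
    u = u * np.sign(u[np.argmax(np.abs(u))] or 1.0)
    side = u >= np.median(u) if (u >= 0).all() or (u < 0).all() else u >= 0
    if side.all() or (~side).all():
        side = np.arange(n) < n // 2
    resp = np.where(side[:, None], [0.95, 0.05], [0.05, 0.95])

    prev_ll = -np.inf
    history: list[float] = []
    weights = resp.mean(axis=0)
    a = np.empty((2, J))
    b = np.empty((2, J))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new_a, new_b = np.empty_like(a), np.empty_like(b)
        for c in range(2):
            new_a[c], new_b[c] = _moment_match(X, resp[:, c] + 1e-12)
        new_weights = np.clip(resp.mean(axis=0), 1e-12, None)
        new_weights /= new_weights.sum()

        log_comp = _log_density(X_log, X1_log, new_a, new_b) + np.log(new_weights)
        ll = float(logsumexp(log_comp, axis=1).sum())
        if ll < prev_ll - tol:
            # moment M-step overshot: keep the previous parameters
            break
        a, b, weights = new_a, new_b, new_weights
        resp = np.exp(log_comp - logsumexp(log_comp, axis=1, keepdims=True))
        history.append(ll)
        if abs(ll - prev_ll) < tol:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll

    return BetaMixtureFit(
        weights=weights, a=a, b=b, resp=resp,
        log_likelihood=prev_ll if history else -np.inf,
        history=history, n_iter=it, converged=converged,
    )


@dataclass
class MixtureNode:
    """One node of the recursive partition: its samples, the one-component
    fit describing them, and (if split) the two children."""

    sample_ids: list
    fit: BetaMixtureFit
    split_score: float = np.nan   # BIC(k=1) − BIC(k=2); > bic_margin ⇒ split
    children: tuple | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class MixtureTree:
    root: MixtureNode

    def leaves(self) -> list[MixtureNode]:
        out: list[MixtureNode] = []

        def walk(node):
            if node.is_leaf:
                out.append(node)
            else:
                for ch in node.children:
                    walk(ch)

        walk(self.root)
        return out

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def labels(self) -> pd.Series:
        """Sample → leaf index (1-based, depth-first order)."""
        rows = {}
        for i, leaf in enumerate(self.leaves(), start=1):
            for s in leaf.sample_ids:
                rows[s] = i
        return pd.Series(rows, name="methylation_class")

    def class_profile(self, beta: pd.DataFrame) -> pd.DataFrame:
        """Per-class mean β over the CpG set (heat-map-style summary)."""
        lab = self.labels()
        return beta.T.groupby(lab.reindex(beta.columns)).mean()


def recursive_partition(
    beta: pd.DataFrame,
    min_node: int = 5,
    bic_margin: float = 0.0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MixtureTree:
    """Recursively split samples with two-component beta-mixture fits.

    ``beta`` is CpGs × samples.  At each node, one- and two-component
    mixtures are fitted; the node splits when
    ``BIC(k=2) + bic_margin < BIC(k=1)`` and both hard-assigned children
    (maximum responsibility) keep at least ``min_node`` samples.  The leaves
    are the discovered methylation classes.
    """
    if beta.shape[1] < min_node:
        raise ValueError("fewer samples than min_node")
    X_all = beta.to_numpy(dtype=float).T  # samples × CpGs
    sample_ids = list(beta.columns)

    def build(idx: np.ndarray) -> MixtureNode:
        X = X_all[idx]
        ids = [sample_ids[i] for i in idx]
        fit1 = fit_beta_mixture(X, k=1, tol=tol, max_iter=max_iter)
        node = MixtureNode(sample_ids=ids, fit=fit1)
        if len(idx) < 2 * min_node:
            return node
        fit2 = fit_beta_mixture(X, k=2, tol=tol, max_iter=max_iter)
        n = len(idx)
        node.split_score = fit1.bic(n) - fit2.bic(n)
        if fit2.bic(n) + bic_margin < fit1.bic(n):
            assign = np.argmax(fit2.resp, axis=1)
            left, right = idx[assign == 0], idx[assign == 1]
            if len(left) >= min_node and len(right) >= min_node:
                node.children = (build(left), build(right))
        return node

    return MixtureTree(root=build(np.arange(len(sample_ids))))


class RecursiveBetaMixture(ClusterMixin, BaseEstimator):
    """Scikit-learn front end for the recursive beta-mixture partition.

    ``fit(X)`` takes samples × CpGs β values and exposes ``labels_``
    (0-based leaf indices), ``n_leaves_`` and the full ``tree_``.
    """

    def __init__(
        self,
        min_node: int = 5,
        bic_margin: float = 0.0,
        tol: float = 1e-6,
        max_iter: int = 500,
    ):
        self.min_node = min_node
        self.bic_margin = bic_margin
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            beta = X.T
        else:
            arr = np.asarray(X, dtype=float)
            beta = pd.DataFrame(
                arr.T, columns=pd.RangeIndex(arr.shape[0])
            )
        self.tree_ = recursive_partition(
            beta,
            min_node=self.min_node,
            bic_margin=self.bic_margin,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        lab = self.tree_.labels().reindex(beta.columns)
        self.labels_ = lab.to_numpy() - 1
        self.n_leaves_ = self.tree_.n_leaves
        return self


def cluster_enrichment(
    cluster_members: pd.Series, attribute: pd.Series
) -> pd.DataFrame:
    """Per-cluster enrichment table for a categorical sample attribute.

    For every (cluster, level) pair reports the member count, the cluster
    size and the enrichment percentage rounded to the nearest integer —
    e.g. 51 of 52 ER-positive members is reported as 98%.
    """
    df = pd.DataFrame({"cluster": cluster_members, "level": attribute}).dropna()
    rows = []
    for cl, sub in df.groupby("cluster"):
        total = len(sub)
        for level, cnt in sub["level"].value_counts().items():
            rows.append(
                {
                    "cluster": cl,
                    "level": level,
                    "count": int(cnt),
                    "cluster_size": total,
                    "percent": enrichment_percent(int(cnt), total),
                }
            )
    return pd.DataFrame(rows)


def enrichment_percent(count: int, total: int) -> int:
    """Enrichment as an integer percentage, round-half-up."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(np.floor(100.0 * count / total + 0.5))
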