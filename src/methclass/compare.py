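"""Class comparison: differential methylation across sample groups.

β values are not Gaussian (bounded, trimodal, variance tied to the mean), so
group comparison uses the rank-based Kruskal–Wallis test per CpG with the
chi-square approximation, followed by family-wise error-rate control.  Holm's
step-down is the default adjustment (uniformly more powerful than Bonferroni
at the same FWER); Bonferroni is available for strict comparability.

The scan is vectorised over CpGs: ranks are taken row-wise, ties get average
ranks with the standard correction divisor 1 − Σ(t³−t)/(N³−N), and H is
referred to chi-square with (groups − 1) degrees of freedom.  For very small
groups a seeded Monte-Carlo permutation p-value is available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import SUBTYPES


def _group_masks(labels: pd.Series, columns, groups=None):
    """Boolean sample masks per group, in sorted group order."""
    labels = pd.Series(labels)
    lab = labels.reindex(columns)
    if lab.isna().any():
        missing = list(pd.Index(columns)[lab.isna()][:5])
        raise ValueError(f"samples without a group label: {missing}")
    if groups is None:
        groups = sorted(lab.unique())
    masks = {}
    for g in groups:
        mask = (lab == g).to_numpy()
        masks[g] = mask
    used = np.logical_or.reduce(list(masks.values()))
    return masks, used


def _tie_correction(row: np.ndarray) -> float:
    """1 − Σ(t³ − t)/(N³ − N) over tie groups of the non-missing values."""
    v = row[~np.isnan(row)]
    n = v.size
    if n < 2:
        return 1.0
    _, counts = np.unique(v, return_counts=True)
    t = counts[counts > 1]
    if t.size == 0:
        return 1.0
    return 1.0 - (t**3 - t).sum() / (n**3 - n)


def kruskal_wallis_matrix(X: np.ndarray, masks: dict) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Kruskal–Wallis H and chi-square p over a values matrix.

    ``X`` is CpGs × samples (NaN = missing, dropped per CpG); ``masks`` maps
    group name → boolean sample mask.  Raises if any group is empty after
    missing-value removal at some CpG.
    """
    X = np.asarray(X, dtype=float)
    if len(masks) < 2:
        raise ValueError("need at least two groups")
    R = stats.rankdata(X, axis=1, nan_policy="omit")
    N = np.sum(~np.isnan(X), axis=1).astype(float)

    H = np.zeros(X.shape[0])
    for mask in masks.values():
        sub = R[:, mask]
        n_g = np.sum(~np.isnan(sub), axis=1).astype(float)
        if (n_g == 0).any():
            bad = int(np.argmax(n_g == 0))
            raise ValueError(
                f"a group is empty after missing-value removal at row {bad}"
            )
        H += np.nansum(sub, axis=1) ** 2 / n_g
    with np.errstate(invalid="ignore", divide="ignore"):
        H = 12.0 / (N * (N + 1.0)) * H - 3.0 * (N + 1.0)

    # tie correction only where ties exist among non-missing values
    S = np.sort(X, axis=1)  # NaN sorts last
    has_tie = np.any(S[:, 1:] == S[:, :-1], axis=1)
    if has_tie.any():
        for i in np.flatnonzero(has_tie):
            H[i] /= _tie_correction(X[i])

    df = len(masks) - 1
    p = stats.chi2.sf(H, df)
    return H, p


def permutation_pvalues(
    X: np.ndarray, masks: dict, n_perm: int = 10000, seed: int = 0
) -> np.ndarray:
    """Monte-Carlo permutation p-values for the row-wise H statistic.

    Group labels are permuted across samples; p = (1 + #{H* ≥ H}) / (1 + B).
    Intended for very small groups where the chi-square approximation is
    doubtful.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    H_obs, _ = kruskal_wallis_matrix(X, masks)
    names = list(masks)
    stack = np.stack([masks[g] for g in names])  # groups × samples
    used = np.flatnonzero(stack.any(axis=0))
    sizes = [int(stack[gi].sum()) for gi in range(len(names))]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    count = np.zeros(X.shape[0])
    for _ in range(n_perm):
        perm = rng.permutation(used)
        pmasks = {}
        for gi, g in enumerate(names):
            m = np.zeros(X.shape[1], dtype=bool)
            m[perm[offsets[gi]: offsets[gi + 1]]] = True
            pmasks[g] = m
        H_perm, _ = kruskal_wallis_matrix(X, pmasks)
        count += H_perm >= H_obs - 1e-12
    return (1.0 + count) / (1.0 + n_perm)


def kruskal_wallis_scan(
    matrix: pd.DataFrame,
    labels: pd.Series,
    groups=None,
    permutation: bool = False,
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Kruskal–Wallis test per CpG across sample groups.

    Parameters
    ----------
    matrix : DataFrame, CpGs × samples
    labels : Series mapping sample id → group
    groups : optional subset of groups to compare (default: all labels present)
    permutation : replace the chi-square p with a seeded Monte-Carlo
        permutation p (for very small groups)

    Returns a DataFrame indexed by cpg_id with columns ``statistic``,
    ``p_value`` and one ``median_<group>`` column per group.
    """
    masks, used = _group_masks(labels, matrix.columns, groups)
    for g, m in masks.items():
        if m.sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    X = matrix.to_numpy(dtype=float)[:, used]
    sub_masks = {g: m[used] for g, m in masks.items()}
    H, p = kruskal_wallis_matrix(X, sub_masks)
    if permutation:
        p = permutation_pvalues(X, sub_masks, n_perm=n_perm, seed=seed)
    out = pd.DataFrame({"statistic": H, "p_value": p}, index=matrix.index)
    for g, m in sub_masks.items():
        out[f"median_{g}"] = np.nanmedian(X[:, m], axis=1)
    return out


def adjust_fwer(p_values, method: str = "holm") -> np.ndarray:
    """Family-wise error-rate adjustment (Holm step-down or Bonferroni).

    Adjusted values are clipped to 1 and are monotone in the sorted p
    sequence; a single p-value is returned unchanged.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("holm", "bonferroni"):
        raise ValueError(f"unknown method {method!r}")
    return multipletests(p, method=method)[1]


def differential_cpgs(
    matrix: pd.DataFrame,
    labels: pd.Series,
    fwer: float = 0.01,
    groups=None,
    method: str = "holm",
    **scan_kwargs,
):
    """Differentially methylated CpGs across tumor subtypes at a FWER bound.

    By default the comparison runs over the four intrinsic subtypes present
    in the labels (normals are excluded); pass ``groups`` explicitly to
    compare something else.  Returns ``(results, selected)``: the full test
    table sorted by adjusted p then cpg_id, and the list of CpG ids with
    ``p_adjusted < fwer``.
    """
    if groups is None:
        present = set(pd.Series(labels).unique())
        groups = [g for g in SUBTYPES if g in present]
        if len(groups) < 2:
            groups = sorted(present)
    results = kruskal_wallis_scan(matrix, labels, groups=groups, **scan_kwargs)
    results = results.copy()
    results["p_adjusted"] = adjust_fwer(results["p_value"].to_numpy(), method=method)
    # ascending adjusted p, ties broken by cpg_id
    results = results.iloc[
        np.lexsort((results.index.to_numpy(), results["p_adjusted"].to_numpy()))
    ]
    selected = results.index[results["p_adjusted"] < fwer].tolist()
    return results, selected
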