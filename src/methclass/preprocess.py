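"""Low-level methylation-array transforms and diagnostics.

The β value is the fraction of methylated signal at a CpG,
``β = Me / (Me + Um + offset)`` with the platform's standard offset of 100
fluorescence units; it lives in [0, 1) and reads as percent methylation.  The
M value is the log2 ratio of methylated to unmethylated intensity — unbounded
and more tractable for variance-based statistics.

Two categorisation schemes are supported.  The *reference* scheme maps β to
the unmethylated / hemi-methylated / methylated reference categories at the
0.2 and 0.8 thresholds; the *holm* scheme discretises to {0, 0.5, 1} at 0.3
and 0.7.  No quantile or LOWESS normalisation is implemented anywhere in this
package: global methylation genuinely differs between samples, so
expression-style normalisation can erase real biology.  The MA transform here
is a diagnostic only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: band edges for MA diagnostics, per mode: (inner, outer)
MA_BANDS = {"beta": (0.2, 0.5), "log_expression": (1.0, 2.0)}

CATEGORIES = ("UM", "HM", "M")


def beta_from_intensities(me, um, offset: float = 100.0):
    """β = Me / (Me + Um + offset); strictly increasing in ``me`` and
    strictly decreasing in ``um``; always in [0, 1)."""
    me = np.asarray(me, dtype=float)
    um = np.asarray(um, dtype=float)
    if offset <= 0:
        raise ValueError("offset must be positive")
    if np.nanmin(me, initial=0) < 0 or np.nanmin(um, initial=0) < 0:
        raise ValueError("intensities must be non-negative")
    return me / (me + um + offset)


def m_from_intensities(me, um, alpha: float = 1.0):
    """M = log2((Me + alpha) / (Um + alpha)).

    ``alpha`` is a pseudo-count keeping the ratio finite at zero intensity
    (default 1); the transform is antisymmetric under swapping Me and Um.
    """
    me = np.asarray(me, dtype=float)
    um = np.asarray(um, dtype=float)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if np.nanmin(me, initial=0) < 0 or np.nanmin(um, initial=0) < 0:
        raise ValueError("intensities must be non-negative")
    return np.log2(me + alpha) - np.log2(um + alpha)


def beta_to_m(beta, eps: float = 1e-6):
    """M value from β: log2(β / (1 − β)) with β clamped to [eps, 1−eps]."""
    b = np.clip(np.asarray(beta, dtype=float), eps, 1 - eps)
    return np.log2(b / (1 - b))


def categorize_beta(beta, scheme: str = "reference"):
    """Categorise β values.

    reference: β < 0.2 → "UM", 0.2 ≤ β ≤ 0.8 → "HM", β > 0.8 → "M".
    holm: β ≤ 0.3 → 0.0, 0.3 < β < 0.7 → 0.5, β ≥ 0.7 → 1.0.  The source
    discretisation leaves β = 0.7 itself unassigned ("> 0.3 and < 0.7" vs
    "> 0.7"); we close the gap upward, so 0.7 maps to 1.

    Scalar input returns a scalar; array input returns an ndarray. NaN is
    propagated (holm) or mapped to None (reference).
    """
    arr = np.asarray(beta, dtype=float)
    valid = ~np.isnan(arr)
    if valid.any() and ((arr[valid] < 0).any() or (arr[valid] > 1).any()):
        raise ValueError("beta values must lie in [0, 1]")
    if scheme == "reference":
        out = np.where(arr < 0.2, "UM", np.where(arr <= 0.8, "HM", "M"))
        out = np.where(valid, out, None)
    elif scheme == "holm":
        out = np.where(arr <= 0.3, 0.0, np.where(arr < 0.7, 0.5, 1.0))
        out = np.where(valid, out, np.nan)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if np.isscalar(beta) or np.ndim(beta) == 0:
        return out.item()
    return out


def ma_transform(sample, reference, mode: str = "beta"):
    """MA diagnostic between a sample and a reference profile.

    For β-valued input the natural scale is the plain difference
    (m = βs − βr, a = (βs + βr)/2); for log2 expression, inputs are already
    on the log scale so m is the log-ratio.  Returns a DataFrame of per-feature
    (m, a) pairs and per-band counts using the conventional display bands
    (β: |m| ≤ 0.2 / ≤ 0.5 / > 0.5; expression: |m| ≤ 1 / ≤ 2 / > 2).
    """
    if mode not in MA_BANDS:
        raise ValueError(f"unknown mode {mode!r}")
    s = np.asarray(sample, dtype=float)
    r = np.asarray(reference, dtype=float)
    if s.shape != r.shape:
        raise ValueError(f"length mismatch: {s.shape} vs {r.shape}")
    m = s - r
    a = (s + r) / 2.0
    index = sample.index if isinstance(sample, pd.Series) else None
    pairs = pd.DataFrame({"m": m, "a": a}, index=index)
    inner, outer = MA_BANDS[mode]
    am = np.abs(m)
    bands = {
        "inner": int(np.sum(am <= inner)),
        "mid": int(np.sum((am > inner) & (am <= outer))),
        "outer": int(np.sum(am > outer)),
    }
    return pairs, bands


def variance_profile(beta, by: str = "observation") -> pd.DataFrame:
    """Per-category summary of β values under the reference scheme.

    ``by="observation"`` categorises every non-missing value; ``by="cpg_mean"``
    categorises each CpG by its across-sample mean (rows of a matrix) and
    pools that CpG's values into the category.  Reports count, fraction,
    mean, median, variance (n−1 denominator) and sd per category.
    """
    if isinstance(beta, pd.DataFrame):
        values = beta.to_numpy(dtype=float)
    else:
        values = np.atleast_2d(np.asarray(beta, dtype=float))
    if np.isnan(values).all():
        raise ValueError("variance_profile: all values missing")

    if by == "observation":
        flat = values.ravel()
        flat = flat[~np.isnan(flat)]
        cats = np.asarray(categorize_beta(flat, "reference"))
        groups = {c: flat[cats == c] for c in CATEGORIES}
    elif by == "cpg_mean":
        row_means = np.nanmean(values, axis=1)
        cats = np.asarray(categorize_beta(row_means, "reference"))
        groups = {}
        for c in CATEGORIES:
            vals = values[cats == c].ravel()
            groups[c] = vals[~np.isnan(vals)]
    else:
        raise ValueError(f"unknown 'by' mode {by!r}")

    total = sum(len(v) for v in groups.values())
    rows = []
    for c in CATEGORIES:
        v = groups[c]
        n = len(v)
        rows.append(
            {
                "category": c,
                "count": n,
                "fraction": n / total if total else np.nan,
                "mean": np.mean(v) if n else np.nan,
                "median": np.median(v) if n else np.nan,
                "variance": np.var(v, ddof=1) if n > 1 else np.nan,
                "sd": np.std(v, ddof=1) if n > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("category")
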