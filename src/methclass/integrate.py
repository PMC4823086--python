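"""Methylation–expression integration.

Promoter methylation is, for the most part, anti-correlated with
transcription.  This module quantifies that structure: it joins CpGs to
expression probes by gene id (keeping either all probes per gene or only the
most variant one), computes the Spearman correlation per mapped pair —
overall and per sample subgroup — and profiles methylation as a function of
signed distance to the transcription start site (TSS), including the
stratification of mean β by expression tier (below the 1st quartile /
between the quartiles / above the 3rd quartile of per-gene mean expression).

Windows over TSS distance are closed intervals on the signed distance
(negative = upstream); quartiles use linear interpolation between order
statistics.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MAP_MODES = ("maximum", "most_variant")
TIERS = ("low", "medium", "high")


def build_gene_map(
    cpg_annot: pd.DataFrame,
    probe_annot: pd.DataFrame,
    expression: pd.DataFrame,
    mode: str = "most_variant",
) -> pd.DataFrame:
    """Join CpGs to expression probes by gene id.

    ``maximum`` keeps every (CpG, probe) pair of a gene (many-to-one by
    gene); ``most_variant`` keeps only the probe with the largest expression
    variance per gene (ties broken by probe id order).  Genes absent from
    either side are dropped with a logged count.

    Returns a DataFrame with columns ``cpg_id``, ``probe_id``, ``gene_id``.
    """
    if mode not in MAP_MODES:
        raise ValueError(f"mode must be one of {MAP_MODES}")
    cpgs = cpg_annot.reset_index()[["cpg_id", "gene_id"]]
    probes = probe_annot.reset_index()[["probe_id", "gene_id"]]
    probes = probes[probes["probe_id"].isin(expression.index)]
    pairs = cpgs.merge(probes, on="gene_id")
    n_genes_cpg = cpgs["gene_id"].nunique()
    n_genes_map = pairs["gene_id"].nunique()
    if pairs.empty:
        raise ValueError("no genes shared between CpG and probe annotation")
    if n_genes_map < n_genes_cpg:
        logger.info(
            "gene map: %d of %d CpG-annotated genes have expression probes",
            n_genes_map, n_genes_cpg,
        )
    if mode == "most_variant":
        var = expression.var(axis=1, ddof=1)
        pairs = pairs.assign(_var=pairs["probe_id"].map(var))
        pairs = pairs.sort_values(["gene_id", "_var", "probe_id"],
                                  ascending=[True, False, True])
        keep = pairs.groupby("gene_id", sort=False)["probe_id"].transform("first")
        pairs = pairs[pairs["probe_id"] == keep].drop(columns="_var")
    return pairs[["cpg_id", "probe_id", "gene_id"]].reset_index(drop=True)


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return stats.spearmanr(x, y).statistic


def correlate(
    beta: pd.DataFrame,
    expression: pd.DataFrame,
    gene_map: pd.DataFrame,
    samples=None,
) -> tuple[pd.DataFrame, dict]:
    """Spearman correlation between β and log2 expression per mapped pair.

    Uses the samples shared by both matrices (optionally restricted to
    ``samples``), pairwise-complete per pair; pairs with fewer than 3
    complete observations raise.  Returns the per-pair records and a summary
    with min/max/mean/median and the fraction of pairs with ρ < 0.
    """
    shared = beta.columns.intersection(expression.columns)
    if samples is not None:
        shared = shared.intersection(pd.Index(samples))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    B = beta.loc[:, shared]
    E = expression.loc[:, shared]
    records = []
    for row in gene_map.itertuples(index=False):
        x = B.loc[row.cpg_id].to_numpy(dtype=float)
        y = E.loc[row.probe_id].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3:
            raise ValueError(
                f"pair ({row.cpg_id}, {row.probe_id}): fewer than 3 complete "
                "observations"
            )
        records.append(
            {
                "cpg_id": row.cpg_id,
                "probe_id": row.probe_id,
                "gene_id": row.gene_id,
                "rho": _spearman(x[ok], y[ok]),
                "n_pairs": int(ok.sum()),
            }
        )
    rec = pd.DataFrame(records)
    rho = rec["rho"].dropna()
    summary = {
        "n_pairs": len(rec),
        "min": float(rho.min()),
        "max": float(rho.max()),
        "mean": float(rho.mean()),
        "median": float(rho.median()),
        "fraction_negative": float((rho < 0).mean()),
    }
    return rec, summary


def correlate_by_group(
    beta: pd.DataFrame,
    expression: pd.DataFrame,
    gene_map: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    groups=None,
) -> pd.DataFrame:
    """Per-group correlation summaries (one row per group)."""
    rows = []
    if groups is None:
        groups = sorted(sample_sheet["group"].unique())
    for g in groups:
        ids = sample_sheet.index[sample_sheet["group"] == g]
        _, summary = correlate(beta, expression, gene_map, samples=ids)
        rows.append({"group": g, **summary})
    return pd.DataFrame(rows).set_index("group")


def tss_window_fraction(cpg_annot: pd.DataFrame, half_width: int) -> float:
    """Fraction of annotated CpGs with |tss_distance| ≤ half_width."""
    if half_width < 0:
        raise ValueError("half_width must be non-negative")
    if cpg_annot.empty:
        raise ValueError("empty annotation")
    d = cpg_annot["tss_distance"].to_numpy()
    return float(np.mean(np.abs(d) <= half_width))


def _tricube_smooth(x: np.ndarray, y: np.ndarray, span: float) -> np.ndarray:
    """Running tricube-weighted mean over positions x (NaN y ignored)."""
    out = np.full_like(y, np.nan, dtype=float)
    half = span * (x.max() - x.min()) / 2.0
    if half <= 0:
        return y.copy()
    for i, xi in enumerate(x):
        w = np.abs(x - xi) / half
        w = np.where(w < 1, (1 - w**3) ** 3, 0.0)
        w = np.where(np.isnan(y), 0.0, w)
        if w.sum() > 0:
            out[i] = np.nansum(w * y) / w.sum()
    return out


def tss_methylation_profile(
    beta: pd.DataFrame,
    cpg_annot: pd.DataFrame,
    bin_width: int = 100,
    smoother_span: float | None = None,
) -> pd.DataFrame:
    """Mean β as a function of signed distance to the TSS.

    Each CpG contributes its across-sample mean β; CpGs are binned by signed
    distance in ``bin_width`` steps.  Empty bins are reported with count 0
    and NaN summaries — never silently interpolated.  ``smoother_span``
    (fraction of the distance range) adds a tricube running-mean column for
    plot-ready curves.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    common = beta.index.intersection(cpg_annot.index)
    if common.empty:
        raise ValueError("no annotated CpGs in the matrix")
    mean_beta = beta.loc[common].mean(axis=1, skipna=True)
    dist = cpg_annot.loc[common, "tss_distance"]
    lo = int(np.floor(dist.min() / bin_width)) * bin_width
    hi = int(np.floor(dist.max() / bin_width)) * bin_width
    edges = np.arange(lo, hi + 2 * bin_width, bin_width)
    which = np.digitize(dist.to_numpy(), edges) - 1
    rows = []
    for i in range(len(edges) - 1):
        vals = mean_beta.to_numpy()[which == i]
        rows.append(
            {
                "bin_left": int(edges[i]),
                "bin_center": float(edges[i] + bin_width / 2.0),
                "count": int(len(vals)),
                "mean_beta": float(np.mean(vals)) if len(vals) else np.nan,
                "median_beta": float(np.median(vals)) if len(vals) else np.nan,
            }
        )
    profile = pd.DataFrame(rows)
    if smoother_span is not None:
        profile["smoothed_beta"] = _tricube_smooth(
            profile["bin_center"].to_numpy(),
            profile["mean_beta"].to_numpy(),
            smoother_span,
        )
    return profile


def expression_tier_summary(
    beta: pd.DataFrame,
    expression: pd.DataFrame,
    gene_map: pd.DataFrame,
    cpg_annot: pd.DataFrame | None = None,
    bin_width: int = 100,
) -> tuple[pd.Series, pd.DataFrame, dict]:
    """Mean promoter methylation stratified by expression tier.

    Per-gene mean expression (across samples, over mapped probes) is split
    at the 1st and 3rd quartiles into low (< Q1), medium (Q1..Q3 inclusive)
    and high (> Q3) tiers; the gene's β is the across-sample mean of its
    mapped CpG(s).  Returns the per-gene tiers, a per-tier β summary (and
    tier-stratified TSS profiles when annotation is supplied), and the
    quartile metadata.  Quartiles use linear interpolation; with constant
    expression every gene is medium (with a warning).
    """
    genes = gene_map["gene_id"].unique()
    if len(genes) < 4:
        raise ValueError("need at least 4 mapped genes to define quartiles")
    expr_gene = (
        expression.loc[gene_map["probe_id"].unique()]
        .mean(axis=1)
        .rename("expr")
        .to_frame()
        .join(gene_map.set_index("probe_id")["gene_id"])
        .groupby("gene_id")["expr"]
        .mean()
    )
    beta_gene = (
        beta.loc[gene_map["cpg_id"].unique()]
        .mean(axis=1)
        .rename("beta")
        .to_frame()
        .join(gene_map.drop_duplicates("cpg_id").set_index("cpg_id")["gene_id"])
        .groupby("gene_id")["beta"]
        .mean()
    )
    q1, q3 = np.quantile(expr_gene.to_numpy(), [0.25, 0.75])
    if q1 == q3:
        warnings.warn("constant expression: all genes assigned to the medium tier")
        tiers = pd.Series("medium", index=expr_gene.index, name="tier")
    else:
        tiers = pd.Series(
            np.where(expr_gene < q1, "low", np.where(expr_gene > q3, "high", "medium")),
            index=expr_gene.index,
            name="tier",
        )
    df = pd.DataFrame({"beta": beta_gene, "tier": tiers}).dropna()
    summary = (
        df.groupby("tier")["beta"]
        .agg(n="size", mean_beta="mean", median_beta="median")
        .reindex(list(TIERS))
    )
    meta = {"q1": float(q1), "q3": float(q3), "quartile_method": "linear"}
    if cpg_annot is not None:
        profiles = {}
        gene_tier = tiers
        cpg_gene = gene_map.drop_duplicates("cpg_id").set_index("cpg_id")["gene_id"]
        for tier in TIERS:
            tier_genes = gene_tier.index[gene_tier == tier]
            tier_cpgs = cpg_gene.index[cpg_gene.isin(tier_genes)]
            if len(tier_cpgs):
                profiles[tier] = tss_methylation_profile(
                    beta.loc[beta.index.intersection(tier_cpgs)],
                    cpg_annot,
                    bin_width=bin_width,
                )
        meta["tss_profiles"] = profiles
    return tiers, summary, meta
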