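"""Synthetic Infinium-27K-style datasets with the statistical structure of
breast-cancer methylation studies.

The generator emulates, at desk scale, the features every downstream module
is designed around:

* a trimodal pooled β density — a dominant hypo-methylation peak, a broad
  hemi-methylated middle, and a minor hyper-methylation peak — obtained by
  assigning each CpG a baseline state in {UM, HM, M} and drawing β from a
  beta distribution per state (defaults UM=Beta(2,18), HM=Beta(2,2),
  M=Beta(18,2), so hemi-methylated CpGs have by far the largest variance);
* four tumor subtypes (Basal, HER2, LumA, LumB) plus normals, with a planted
  set of subtype-differential CpGs whose state depends on the subtype; the
  planted truth is returned so recovery can be scored exactly;
* promoter-proximal CpG placement (a configurable fraction of CpGs within
  ±500 bp of the TSS) and log2 expression that decreases with promoter
  methylation, with the slope attenuated outside the promoter window.

Fixing ``SimConfig.seed`` makes every output byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SUBTYPES

STATES = ("UM", "HM", "M")

#: ER status typically associated with each group: luminal subtypes are
#: ER-positive, Basal and most HER2-enriched tumors ER-negative.
_ER_BY_GROUP = {
    "Normal": "unknown", "Basal": "neg", "HER2": "neg", "LumA": "pos", "LumB": "pos",
}


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults are the study conditions the package is tested under: four
    subtypes of 30 tumors each plus 8 normals, 5000 CpGs (one per gene) of
    which 99 are planted as subtype-differential, baseline state proportions
    0.55 / 0.25 / 0.20 for UM / HM / M.
    """

    n_cpgs: int = 5000
    n_tumors_per_subtype: int = 30
    n_normals: int = 8
    frac_unmethylated: float = 0.55
    frac_hemi: float = 0.25
    frac_methylated: float = 0.20
    n_differential: int = 99
    #: per-state (a, b) shapes of the beta distribution on [0, 1]
    beta_params: dict = field(
        default_factory=lambda: {
            "UM": (2.0, 18.0), "HM": (2.0, 2.0), "M": (18.0, 2.0),
        }
    )
    #: 1.0 = full separation between differential states; smaller values
    #: shrink the differential-state means toward 0.5 (harder problems)
    effect_size: float = 1.0
    #: fraction of CpGs placed within ±promoter_window bp of the TSS
    promoter_fraction: float = 0.78
    promoter_window: int = 500
    max_tss_distance: int = 5000
    probes_per_gene_max: int = 3
    expr_baseline_mean: float = 8.0
    expr_baseline_sd: float = 1.5
    #: log2 expression drop per unit β for promoter-window CpGs
    expr_slope: float = 4.0
    expr_noise_sd: float = 0.5
    #: slope multiplier for CpGs outside the promoter window
    distal_slope_factor: float = 0.25
    seed: int = 0

    def __post_init__(self):
        fracs = (self.frac_unmethylated, self.frac_hemi, self.frac_methylated)
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"state proportions must sum to 1, got {fracs}")
        for state, (a, b) in self.beta_params.items():
            if a <= 0 or b <= 0:
                raise ValueError(f"beta shapes must be positive, got {state}=({a},{b})")
        if self.n_differential > self.n_cpgs:
            raise ValueError("n_differential cannot exceed n_cpgs")
        if not 0 < self.effect_size <= 1:
            raise ValueError("effect_size must be in (0, 1]")

    @property
    def state_fractions(self) -> tuple[float, float, float]:
        return (self.frac_unmethylated, self.frac_hemi, self.frac_methylated)

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SimulatedDataset:
    """All pieces of one simulated study series."""

    beta: pd.DataFrame           # CpGs × samples, β in [0, 1]
    samples: pd.DataFrame        # sample sheet (group, er_status)
    truth: pd.DataFrame          # per-CpG baseline state + planted subtype states
    cpg_annotation: pd.DataFrame
    probe_annotation: pd.DataFrame
    expression: pd.DataFrame | None = None  # probes × samples, log2 scale


def _rng(config: SimConfig, rng=None) -> np.random.Generator:
    return np.random.default_rng(config.seed) if rng is None else rng


def _cpg_ids(n: int) -> list[str]:
    return [f"cg{i:06d}" for i in range(n)]


def _gene_ids(n: int) -> list[str]:
    return [f"gene{i:06d}" for i in range(n)]


def generate_annotation(config: SimConfig, rng=None):
    """Generate CpG and expression-probe annotation.

    One CpG per gene (the 27K design targets one to two promoter CpGs per
    gene); each gene gets 1..probes_per_gene_max expression probes so both
    gene-mapping modes are exercised.  A ``promoter_fraction`` of CpGs gets a
    signed TSS distance in [-promoter_window, promoter_window]; the rest lie
    between the window edge and ``max_tss_distance`` on either side.
    """
    rng = _rng(config, rng)
    n = config.n_cpgs
    genes = _gene_ids(n)
    w = config.promoter_window
    in_window = rng.random(n) < config.promoter_fraction
    dist = np.where(
        in_window,
        rng.integers(-w, w + 1, size=n),
        rng.integers(w + 1, config.max_tss_distance + 1, size=n)
        * rng.choice([-1, 1], size=n),
    )
    cpg_annot = pd.DataFrame(
        {"gene_id": genes, "tss_distance": dist.astype(int)},
        index=pd.Index(_cpg_ids(n), name="cpg_id"),
    )
    n_probes = rng.integers(1, config.probes_per_gene_max + 1, size=n)
    probe_ids, probe_genes = [], []
    for g, k in zip(genes, n_probes):
        for j in range(k):
            probe_ids.append(f"pb_{g}_{j}")
            probe_genes.append(g)
    probe_annot = pd.DataFrame(
        {"gene_id": probe_genes}, index=pd.Index(probe_ids, name="probe_id")
    )
    return cpg_annot, probe_annot


def assign_states(config: SimConfig, rng=None) -> pd.DataFrame:
    """Draw the per-CpG truth: a baseline state, and for the planted
    differential CpGs a non-constant subtype → state map.

    Normals (and all samples at non-differential CpGs) carry the baseline
    state; tumors of subtype g carry ``state_<g>`` at differential CpGs.
    """
    rng = _rng(config, rng)
    n = config.n_cpgs
    baseline = rng.choice(STATES, size=n, p=config.state_fractions)
    truth = pd.DataFrame(
        {"baseline_state": baseline, "is_differential": False},
        index=pd.Index(_cpg_ids(n), name="cpg_id"),
    )
    for g in SUBTYPES:
        truth[f"state_{g}"] = baseline
    if config.n_differential:
        diff_idx = np.sort(
            rng.choice(n, size=config.n_differential, replace=False)
        )
        truth.iloc[diff_idx, truth.columns.get_loc("is_differential")] = True
        for i in diff_idx:
            # uniform over non-constant subtype→state maps (rejection sampling)
            while True:
                states = rng.choice(STATES, size=len(SUBTYPES))
                if len(set(states)) > 1:
                    break
            for g, s in zip(SUBTYPES, states):
                truth.iloc[i, truth.columns.get_loc(f"state_{g}")] = s
    return truth


def make_sample_sheet(config: SimConfig, prefix: str = "") -> pd.DataFrame:
    """Deterministic sample sheet: normals first, then tumors by subtype."""
    rows = []
    for i in range(config.n_normals):
        rows.append((f"{prefix}Normal{i + 1:02d}", "Normal"))
    for g in SUBTYPES:
        for i in range(config.n_tumors_per_subtype):
            rows.append((f"{prefix}{g}{i + 1:02d}", g))
    sheet = pd.DataFrame(rows, columns=["sample_id", "group"]).set_index("sample_id")
    sheet["er_status"] = sheet["group"].map(_ER_BY_GROUP)
    return sheet


def _effective_shapes(config: SimConfig, adjusted: bool) -> dict:
    """Per-state shapes, with differential-CpG means shrunk toward 0.5 by
    (1 - effect_size) at the same concentration a+b."""
    shapes = {}
    for s, (a, b) in config.beta_params.items():
        if adjusted and config.effect_size < 1:
            c = a + b
            mu = 0.5 + config.effect_size * (a / c - 0.5)
            shapes[s] = (mu * c, (1 - mu) * c)
        else:
            shapes[s] = (float(a), float(b))
    return shapes


def draw_beta(
    truth: pd.DataFrame, sheet: pd.DataFrame, config: SimConfig, rng=None
) -> pd.DataFrame:
    """Draw a β matrix (CpGs × samples) given the truth and a sample sheet."""
    rng = _rng(config, rng)
    state_index = {s: i for i, s in enumerate(STATES)}
    n_cpg, n_samp = len(truth), len(sheet)

    state_mat = np.empty((n_cpg, n_samp), dtype=np.int8)
    adjusted = np.zeros((n_cpg, n_samp), dtype=bool)
    baseline_codes = truth["baseline_state"].map(state_index).to_numpy()
    is_diff = truth["is_differential"].to_numpy()
    for j, (sid, row) in enumerate(sheet.iterrows()):
        g = row["group"]
        if g == "Normal":
            state_mat[:, j] = baseline_codes
        else:
            codes = truth[f"state_{g}"].map(state_index).to_numpy()
            state_mat[:, j] = codes
            adjusted[is_diff, j] = True

    base = np.array([config.beta_params[s] for s in STATES])
    adj = np.array([_effective_shapes(config, True)[s] for s in STATES])
    a = np.where(adjusted, adj[state_mat, 0], base[state_mat, 0])
    b = np.where(adjusted, adj[state_mat, 1], base[state_mat, 1])
    values = rng.beta(a, b)
    return pd.DataFrame(values, index=truth.index, columns=sheet.index)


def generate_methylation(config: SimConfig, rng=None, truth=None, prefix: str = ""):
    """Generate a β matrix, sample sheet and planted truth.

    Passing a precomputed ``truth`` reuses the same planted structure with
    fresh noise — that is how paired training/test series are made.
    """
    rng = _rng(config, rng)
    if truth is None:
        truth = assign_states(config, rng)
    sheet = make_sample_sheet(config, prefix=prefix)
    beta = draw_beta(truth, sheet, config, rng)
    return beta, sheet, truth


def generate_expression(
    beta: pd.DataFrame,
    cpg_annot: pd.DataFrame,
    probe_annot: pd.DataFrame,
    config: SimConfig,
    rng=None,
) -> pd.DataFrame:
    """Generate a log2 expression matrix anti-correlated with promoter β.

    Each probe of a gene reads ``baseline − slope·β + noise`` where β is the
    gene's promoter CpG in the given matrix; the slope is ``expr_slope``
    inside the promoter window and attenuated by ``distal_slope_factor``
    outside it.  Genes with no CpG in ``beta`` get baseline plus noise only.
    """
    rng = _rng(config, rng)
    gene_to_cpg = pd.Series(cpg_annot.index.values, index=cpg_annot["gene_id"].values)
    in_window = (cpg_annot["tss_distance"].abs() <= config.promoter_window)
    cpg_slope = np.where(
        in_window, config.expr_slope, config.expr_slope * config.distal_slope_factor
    )
    cpg_slope = pd.Series(cpg_slope, index=cpg_annot.index)

    n_probes, n_samp = len(probe_annot), beta.shape[1]
    baseline = rng.normal(config.expr_baseline_mean, config.expr_baseline_sd, n_probes)
    noise = (
        rng.normal(0.0, config.expr_noise_sd, size=(n_probes, n_samp))
        if config.expr_noise_sd > 0
        else np.zeros((n_probes, n_samp))
    )
    values = baseline[:, None] + noise
    probe_cpg = probe_annot["gene_id"].map(gene_to_cpg)
    usable = probe_cpg.notna() & probe_cpg.isin(beta.index)
    if usable.any():
        rows = probe_cpg[usable]
        slopes = cpg_slope.loc[rows].to_numpy()[:, None]
        values[usable.to_numpy()] -= slopes * beta.loc[rows].to_numpy()
    return pd.DataFrame(values, index=probe_annot.index, columns=beta.columns)


def simulate_dataset(config: SimConfig, with_expression: bool = True) -> SimulatedDataset:
    """Generate one complete series (annotation, methylation, expression)."""
    rng = np.random.default_rng(config.seed)
    cpg_annot, probe_annot = generate_annotation(config, rng)
    beta, sheet, truth = generate_methylation(config, rng)
    expr = (
        generate_expression(beta, cpg_annot, probe_annot, config, rng)
        if with_expression
        else None
    )
    return SimulatedDataset(beta, sheet, truth, cpg_annot, probe_annot, expr)


def simulate_train_test(config: SimConfig, with_expression: bool = True):
    """Generate a training and a test series sharing the planted truth.

    Mirrors the paired-series design of two-cohort studies: identical planted
    structure, independent measurement noise; expression (if requested) only
    for the training series.
    """
    rng = np.random.default_rng(config.seed)
    cpg_annot, probe_annot = generate_annotation(config, rng)
    truth = assign_states(config, rng)
    beta1, sheet1, _ = generate_methylation(config, rng, truth=truth, prefix="s1_")
    beta2, sheet2, _ = generate_methylation(config, rng, truth=truth, prefix="s2_")
    expr = (
        generate_expression(beta1, cpg_annot, probe_annot, config, rng)
        if with_expression
        else None
    )
    train = SimulatedDataset(beta1, sheet1, truth, cpg_annot, probe_annot, expr)
    test = SimulatedDataset(beta2, sheet2, truth, cpg_annot, probe_annot, None)
    return train, test


def write_dataset(ds: SimulatedDataset, out_dir) -> None:
    """Write all dataset pieces as TSV into ``out_dir``."""
    from pathlib import Path

    from . import io as mio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mio.write_matrix(ds.beta, out / "beta.tsv")
    mio.write_sample_sheet(ds.samples, out / "samples.tsv")
    ds.truth.to_csv(out / "truth.tsv", sep="\t")
    mio.write_annotation(ds.cpg_annotation, out / "cpg_annotation.tsv", "cpg_id")
    mio.write_annotation(ds.probe_annotation, out / "probe_annotation.tsv", "probe_id")
    if ds.expression is not None:
        mio.write_matrix(ds.expression, out / "expression.tsv")
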