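"""End-to-end pipeline: simulate → preprocess → filter → compare → predict →
discover → integrate, driven by one config mapping.

The pipeline is deliberately synthetic-data-first: the ``simulate`` stage
produces a paired training/test series with planted truth, and every later
stage consumes the outputs of earlier ones.  External β/expression matrices
can be supplied instead of simulating, in which case the stages that need a
train/test split (predict) or planted truth must be disabled or given their
inputs explicitly.

Every run writes a ``manifest.json`` recording the config hash, seeds,
package version and per-stage row counts — no timestamps, so a rerun with
the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__, compare, discover, integrate
from . import io as mio
from . import predict as mpredict
from . import preprocess, selectors, simulate

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate", "preprocess", "filter", "compare", "predict", "discover", "integrate",
)


class PipelineConfigError(ValueError):
    """Raised when a pipeline config is inconsistent."""


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def validate_config(config: dict) -> dict:
    cfg = dict(config)
    stages = list(cfg.get("stages", ALL_STAGES))
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        raise PipelineConfigError(f"unknown stages: {unknown}")
    cfg["stages"] = stages
    cfg.setdefault("seed", 0)
    if "predict" in stages and "simulate" not in stages:
        if not (cfg.get("inputs", {}).get("test_beta")):
            raise PipelineConfigError(
                "predict requires a train/test split: enable the simulate stage "
                "or provide inputs.test_beta and inputs.test_samples"
            )
    needs_sim = {"filter", "compare", "discover", "integrate"} & set(stages)
    if needs_sim and "simulate" not in stages and "beta" not in cfg.get("inputs", {}):
        raise PipelineConfigError(
            "provide inputs.beta/inputs.samples or enable the simulate stage"
        )
    return cfg


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the configured stages in dependency order.

    Returns the manifest dictionary (also written to ``out_dir``); a stage
    failure aborts with the failing stage named, retaining partial outputs.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = {
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "version": __version__,
        "stages": [],
    }
    state: dict = {}

    def record(name, **counts):
        manifest["stages"].append({"name": name, "status": "complete", **counts})
        logger.info("stage %s complete: %s", name, counts)

    try:
        for stage in [s for s in ALL_STAGES if s in cfg["stages"]]:
            if stage == "simulate":
                sim_cfg = simulate.SimConfig(**{**cfg.get("simulate", {}), "seed": seed})
                train, test = simulate.simulate_train_test(sim_cfg)
                simulate.write_dataset(train, out / "train")
                simulate.write_dataset(test, out / "test")
                state.update(train=train, test=test)
                record(
                    stage,
                    n_cpgs=train.beta.shape[0],
                    n_train_samples=train.beta.shape[1],
                    n_test_samples=test.beta.shape[1],
                )
            elif stage == "preprocess":
                beta = _train_beta(state, cfg)
                m_values = pd.DataFrame(
                    preprocess.beta_to_m(beta.to_numpy()),
                    index=beta.index, columns=beta.columns,
                )
                mio.write_matrix(m_values, out / "m_values.tsv")
                profile = preprocess.variance_profile(beta)
                profile.to_csv(out / "variance_profile.tsv", sep="\t")
                cats = pd.DataFrame(
                    preprocess.categorize_beta(beta.to_numpy(), "holm"),
                    index=beta.index, columns=beta.columns,
                )
                mio.write_matrix(cats, out / "categories_holm.tsv")
                record(stage, n_cpgs=beta.shape[0])
            elif stage == "filter":
                beta, sheet = _train_beta(state, cfg), _train_sheet(state, cfg)
                fcfg = cfg.get("filter", {})
                method = fcfg.get("method", "test")
                if method == "variance":
                    res = selectors.top_variance_filter(beta, k=int(fcfg.get("k", 100)))
                elif method == "differential":
                    tumor = beta.loc[:, sheet.index[sheet["group"] != "Normal"]]
                    normal = beta.loc[:, sheet.index[sheet["group"] == "Normal"]]
                    res = selectors.differential_filter(
                        tumor, normal,
                        delta=float(fcfg.get("delta", 0.2)),
                        min_frac=float(fcfg.get("min_frac", 0.3)),
                        direction=fcfg.get("direction", "both"),
                    )
                elif method == "test":
                    res = selectors.rank_by_test(
                        beta, sheet["group"],
                        fwer_threshold=float(fcfg.get("fwer", 0.01)),
                    )
                else:
                    raise PipelineConfigError(f"unknown filter method {method!r}")
                pd.DataFrame(
                    {"cpg_id": res.selected}
                ).to_csv(out / "selected_cpgs.tsv", sep="\t", index=False)
                state["selected"] = res.selected
                record(stage, n_selected=len(res.selected), method=method)
            elif stage == "compare":
                beta, sheet = _train_beta(state, cfg), _train_sheet(state, cfg)
                ccfg = cfg.get("compare", {})
                results, selected = compare.differential_cpgs(
                    beta, sheet["group"], fwer=float(ccfg.get("fwer", 0.01))
                )
                results.to_csv(out / "class_comparison.tsv", sep="\t")
                state.setdefault("selected", selected)
                record(stage, n_tested=len(results), n_significant=len(selected))
            elif stage == "predict":
                pcfg = cfg.get("predict", {})
                train, test = state["train"], state["test"]
                cpgs = state.get("selected") or list(train.beta.index)
                model = mpredict.build_centroids(
                    train.beta, train.samples["group"], cpgs
                )
                detail = mpredict.predict_nearest_centroid(test.beta.loc[cpgs], model)
                truth_labels = test.samples["group"].reindex(detail.index)
                tumors = truth_labels != "Normal"
                conf = mpredict.confusion_and_error(
                    truth_labels[tumors], detail["predicted"][tumors]
                )
                detail.to_csv(out / "predictions_ncc.tsv", sep="\t")
                conf.counts.to_csv(out / "confusion_ncc.tsv", sep="\t")
                counts = {"ncc_overall_error": round(conf.overall_error, 4)}
                if "rf" in pcfg.get("methods", ["ncc", "rf"]):
                    rf_pred = mpredict.random_forest_predict(
                        train.beta, train.samples["group"], test.beta,
                        cpg_set=cpgs,
                        n_trees=int(pcfg.get("n_trees", 500)),
                        seed=seed,
                    )
                    rf_conf = mpredict.confusion_and_error(
                        truth_labels[tumors], rf_pred[tumors]
                    )
                    rf_conf.counts.to_csv(out / "confusion_rf.tsv", sep="\t")
                    counts["rf_overall_error"] = round(rf_conf.overall_error, 4)
                record(stage, n_test=int(tumors.sum()), **counts)
            elif stage == "discover":
                dcfg = cfg.get("discover", {})
                beta = (
                    state["test"].beta if "test" in state else _train_beta(state, cfg)
                )
                sheet = (
                    state["test"].samples if "test" in state
                    else _train_sheet(state, cfg)
                )
                tumors = sheet.index[sheet["group"] != "Normal"]
                cpgs = state.get("selected") or list(beta.index)
                sub = beta.loc[cpgs, tumors]
                method = dcfg.get("method", "rpmm")
                if method == "hclust":
                    dend, support = discover.bootstrap_support(
                        sub,
                        B=int(dcfg.get("B", 1000)),
                        seed=seed,
                        compute_au=bool(dcfg.get("compute_au", False)),
                    )
                    (out / "dendrogram.nwk").write_text(dend.to_newick() + "\n")
                    support.to_csv(out / "support.tsv", sep="\t", index=False)
                    classes = dend.cut(int(dcfg.get("cut_k", 4)))
                    n_classes = classes.nunique()
                else:
                    tree = discover.recursive_partition(
                        sub,
                        min_node=int(dcfg.get("min_node", 5)),
                        bic_margin=float(dcfg.get("bic_margin", 0.0)),
                    )
                    classes = tree.labels()
                    tree.class_profile(sub).to_csv(out / "class_profile.tsv", sep="\t")
                    n_classes = tree.n_leaves
                classes.rename("methylation_class").to_csv(
                    out / "classes.tsv", sep="\t", index_label="sample_id"
                )
                record(stage, method=method, n_classes=int(n_classes))
            elif stage == "integrate":
                icfg = cfg.get("integrate", {})
                train = state.get("train")
                if train is None or train.expression is None:
                    raise PipelineConfigError("integrate requires expression data")
                gmap = integrate.build_gene_map(
                    train.cpg_annotation, train.probe_annotation,
                    train.expression, mode=icfg.get("mode", "most_variant"),
                )
                _, summary = integrate.correlate(train.beta, train.expression, gmap)
                by_group = integrate.correlate_by_group(
                    train.beta, train.expression, gmap, train.samples
                )
                by_group.to_csv(out / "correlations_by_group.tsv", sep="\t")
                profile = integrate.tss_methylation_profile(
                    train.beta, train.cpg_annotation,
                    bin_width=int(icfg.get("bin_width", 100)),
                    smoother_span=icfg.get("smoother_span", 0.2),
                )
                profile.to_csv(out / "tss_profile.tsv", sep="\t", index=False)
                _, tier_summary, _ = integrate.expression_tier_summary(
                    train.beta, train.expression, gmap
                )
                tier_summary.to_csv(out / "tier_summary.tsv", sep="\t")
                record(
                    stage,
                    n_pairs=summary["n_pairs"],
                    fraction_negative=round(summary["fraction_negative"], 4),
                )
    except PipelineConfigError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        failed = stage
        manifest["stages"].append({"name": failed, "status": "failed", "error": str(exc)})
        _write_manifest(manifest, out)
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _train_beta(state: dict, cfg: dict) -> pd.DataFrame:
    if "train" in state:
        return state["train"].beta
    if "beta" not in state:
        state["beta"] = mio.read_matrix(cfg["inputs"]["beta"], "beta")
    return state["beta"]


def _train_sheet(state: dict, cfg: dict) -> pd.DataFrame:
    if "train" in state:
        return state["train"].samples
    if "sheet" not in state:
        state["sheet"] = mio.read_sample_sheet(cfg["inputs"]["samples"])
    return state["sheet"]
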