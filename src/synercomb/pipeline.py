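"""Top-level pipeline orchestration: simulate -> score -> featurize ->
train -> evaluate -> rank -> rules.

Every stage reads its inputs from, and persists its outputs to, the
configured working directory, so any stage can be re-run from the
preceding artifacts and the whole chain is reproducible bit-for-bit for
a fixed seed and configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.ensemble import RandomForestRegressor

from . import io as sio
from .dose_response import MonoSummary, summarize_mono
from .featurize import FeatureSchema, build_feature_matrix, build_panel
from .loewe import fit_mono, synergy_score
from .modeling import (
    SynergyClassification,
    SynergyRegression,
    split_data,
)
from .rules import mine_rules, rules_to_frame, subset_view
from .simulate import SimulationConfig, simulate_study

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

#: Reduced forest grids used by the pipeline defaults; sized for
#: desk-scale studies so a full run stays in the minutes range on one
#: CPU. The full family grids remain available through ModelSpec.
PIPELINE_FOREST_GRID = {"n_estimators": [200], "max_features": ["sqrt", 0.3],
                        "min_samples_leaf": [1, 5]}
PIPELINE_FOREST_GRID_CLF = {"n_estimators": [200], "max_features": ["sqrt"],
                            "min_samples_leaf": [1, 5]}


@dataclass
class PipelineConfig:
    """Paths, model choices and stage parameters for one pipeline run."""

    workdir: str = "synercomb_run"
    seed: int = 0
    regression_family: str = "extra_trees"
    classification_family: str = "extra_trees"
    thresholds: tuple[float, ...] = (0.0, 10.0, 15.0, 20.0)
    rule_s_min: float = 15.0
    rule_max_len: int = 4
    rule_min_support: int = 20
    rule_top_k: int = 10
    average_replicates: bool = False
    log_level: str = "INFO"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if any(t < 0 for t in self.thresholds):
            raise ValueError("classification thresholds must be non-negative")

    @property
    def paths(self) -> dict[str, Path]:
        w = Path(self.workdir)
        return {
            "experiments": w / "experiments.csv",
            "gene_sets": w / "gene_sets.gmt",
            "mutation": w / "mutation.tsv",
            "expression": w / "expression.tsv",
            "cnv": w / "cnv.tsv",
            "targets": w / "drug_targets.tsv",
            "sl": w / "sl_pairs.tsv",
            "truth": w / "truth.csv",
            "scores": w / "scores.csv",
            "mono_summaries": w / "mono_summaries.csv",
            "features": w / "features.csv",
            "split": w / "split.json",
            "model": w / "model.pkl",
            "report": w / "report.json",
            "report_txt": w / "report.txt",
            "ranking": w / "ranking.csv",
            "rules": w / "rules.tsv",
        }

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        if "thresholds" in raw:
            raw["thresholds"] = tuple(raw["thresholds"])
        return cls(simulation=sim, **raw)

    def config_hash(self) -> str:
        payload = {**asdict(self)}
        payload.pop("workdir", None)   # where artifacts live does not
        payload.pop("log_level", None)  # change what is computed
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _ensure_workdir(config: PipelineConfig) -> Path:
    w = Path(config.workdir)
    w.mkdir(parents=True, exist_ok=True)
    return w


def stage_simulate(config: PipelineConfig):
    _ensure_workdir(config)
    study = simulate_study(config.simulation)
    sio.write_study(study, config.workdir)
    logger.info("simulate: %d experiments written", len(study.experiments))
    return study


def stage_score(config: PipelineConfig) -> pd.DataFrame:
    """Loewe-score every deduplicated experiment; persist scores and
    per-(cell line, drug) mono-therapy summaries."""
    p = config.paths
    experiments = sio.deduplicate(sio.read_experiments(p["experiments"]))
    samples = [synergy_score(e) for e in experiments]
    sio.write_scores(samples, p["scores"])

    summaries: dict[tuple[str, str], MonoSummary] = {}
    for e in experiments:
        for curve in (e.mono_a, e.mono_b):
            key = (curve.cell_line_id, curve.drug_id)
            if key not in summaries:
                summaries[key] = summarize_mono(curve, fit_mono(curve))
    pd.DataFrame([
        {"cell_line": c, "drug": d, "ic50": s.ic50, "dss": s.dss,
         "e_inf": s.e_inf}
        for (c, d), s in sorted(summaries.items())
    ]).to_csv(p["mono_summaries"], index=False)
    return sio.read_scores(p["scores"])


def _load_featurize_inputs(config: PipelineConfig):
    p = config.paths
    panel = build_panel(sio.read_gmt(p["gene_sets"]))
    profiles = sio.read_profiles(p["mutation"], p["expression"], p["cnv"])
    drugs = sio.read_drug_targets(p["targets"])
    sl = sio.read_sl_table(p["sl"])
    scores = sio.read_scores(p["scores"])
    mono = pd.read_csv(p["mono_summaries"])
    summaries = {
        (r.cell_line, r.drug): MonoSummary(r.ic50, r.dss, r.e_inf)
        for r in mono.itertuples(index=False)
    }
    return panel, profiles, drugs, sl, scores, summaries


def stage_featurize(config: PipelineConfig):
    """Split, then encode every scored sample (leakage-safe by fold)."""
    p = config.paths
    panel, profiles, drugs, sl, scores, summaries = _load_featurize_inputs(config)
    split = split_data(len(scores), config.seed)
    with open(p["split"], "w") as fh:
        json.dump({"seed": split.seed,
                   "train": split.train_idx.tolist(),
                   "test": split.test_idx.tolist(),
                   "folds": [f.tolist() for f in split.folds]}, fh)
    schema = FeatureSchema.from_panel(panel, drugs)
    train_mask = np.zeros(len(scores), dtype=bool)
    train_mask[split.train_idx] = True
    addition = {
        (r.cell_line, r.drug_a, r.drug_b): r.addition_score
        for r in scores.itertuples(index=False)
    }
    X = build_feature_matrix(scores, profiles, drugs, schema, summaries,
                             addition, sl, train_mask)
    sio.write_feature_matrix(X, schema, scores, p["features"])
    return X, schema, split


def _load_split(path):
    with open(path) as fh:
        raw = json.load(fh)
    from .modeling import DataSplit
    return DataSplit(train_idx=np.array(raw["train"]),
                     test_idx=np.array(raw["test"]),
                     folds=tuple(np.array(f) for f in raw["folds"]),
                     seed=raw["seed"])


def _forest_grid(family: str, task: str):
    if family in ("random_forest", "extra_trees"):
        return PIPELINE_FOREST_GRID if task == "regression" else PIPELINE_FOREST_GRID_CLF
    return None


def stage_train(config: PipelineConfig):
    p = config.paths
    X, schema, meta = sio.read_feature_matrix(p["features"])
    scores = sio.read_scores(p["scores"])
    split = _load_split(p["split"])
    model = SynergyRegression(
        X, scores["synergy_score"].to_numpy(), scores, split,
        family=config.regression_family,
        grid=_forest_grid(config.regression_family, "regression"),
        seed=config.seed)
    results = model.fit()
    with open(p["model"], "wb") as fh:
        pickle.dump(results.trained, fh)
    logger.info("train: %s chose %s (CV r=%.3f)", config.regression_family,
                results.params, results.cv_score)
    return results


def stage_evaluate(config: PipelineConfig, regression_results=None) -> dict:
    p = config.paths
    X, schema, meta = sio.read_feature_matrix(p["features"])
    scores = sio.read_scores(p["scores"])
    split = _load_split(p["split"])
    y = scores["synergy_score"].to_numpy()

    if regression_results is None:
        with open(p["model"], "rb") as fh:
            trained = pickle.load(fh)
        from .modeling import SynergyRegressionResults
        model = SynergyRegression(X, y, scores, split,
                                  family=trained.spec.family,
                                  grid=trained.spec.grid, seed=config.seed)
        regression_results = SynergyRegressionResults(model, trained)
    reg_report = regression_results.evaluate()

    f1s = {}
    for thr in config.thresholds:
        clf = SynergyClassification(
            X, y, scores, split, threshold=thr,
            family=config.classification_family,
            grid=_forest_grid(config.classification_family, "classification"),
            seed=config.seed)
        f1s[thr] = clf.fit().f1_test()
    reg_report.f1_by_threshold = f1s

    report = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "regression": {
            "family": config.regression_family,
            "params": {k: str(v) for k, v in regression_results.params.items()},
            "cv_pearson_r": regression_results.cv_score,
            **reg_report.to_dict(),
        },
        "classification": {
            "family": config.classification_family,
            "f1_by_threshold": {str(k): v for k, v in f1s.items()},
        },
    }
    with open(p["report"], "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(p["report_txt"], "w") as fh:
        fh.write(regression_results.summary() + "\n\nF1 by threshold:\n")
        for thr, f1 in sorted(f1s.items()):
            fh.write(f"  +/-{thr:g}: {f1:.4f}\n")
    return report


def stage_rank(config: PipelineConfig) -> pd.DataFrame:
    p = config.paths
    with open(p["report"]) as fh:
        report = json.load(fh)
    rows = [
        {"cell_line": cell, "best_pair": ".".join(v["best_pair"]),
         "predicted_rank": v["predicted_rank"], "n_candidates": v["n"]}
        for cell, v in sorted(report["regression"]["ranking"].items())
    ]
    df = pd.DataFrame(rows)
    df.to_csv(p["ranking"], index=False)
    return df


#: Hyperparameters of the interpretable rule-mining forest. Trained on
#: the genomic/target/SL blocks only; shallow trees keep decision paths
#: rule-sized so identical canonical signatures recur across the ensemble.
RULE_FOREST_PARAMS = {"n_estimators": 600, "max_depth": 3,
                      "min_samples_leaf": 10, "max_features": 0.6}


def stage_rules(config: PipelineConfig):
    p = config.paths
    X, schema, meta = sio.read_feature_matrix(p["features"])
    scores = sio.read_scores(p["scores"])
    split = _load_split(p["split"])
    y = scores["synergy_score"].to_numpy()

    cols = []
    for block in ("mutation", "expression", "cnv_amp", "cnv_del", "targets", "sl"):
        sl_ = schema.block_slice(block)
        cols.extend(range(sl_.start, sl_.stop))
    view = subset_view(schema, cols)
    forest = RandomForestRegressor(random_state=config.seed, n_jobs=1,
                                   **RULE_FOREST_PARAMS)
    tr = split.train_idx
    forest.fit(X[np.ix_(tr, cols)], y[tr])
    rules = mine_rules(forest, view, X[np.ix_(tr, cols)], y[tr],
                       s_min=config.rule_s_min, max_len=config.rule_max_len,
                       min_support=config.rule_min_support,
                       top_k=config.rule_top_k, interpretable_only=True)
    rules_to_frame(rules).to_csv(p["rules"], sep="\t", index=False)
    return rules


def run_pipeline(config: PipelineConfig, simulate: bool = True) -> dict:
    """Execute all stages in order; returns the evaluation report."""
    logging.basicConfig(level=config.log_level)
    t0 = time.time()
    stages = ([("simulate", stage_simulate)] if simulate else []) + [
        ("score", stage_score),
        ("featurize", stage_featurize),
        ("train", stage_train),
    ]
    results = None
    for name, fn in stages:
        t = time.time()
        try:
            out = fn(config)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        if name == "train":
            results = out
        logger.info("stage %s: %.1fs", name, time.time() - t)
    report = stage_evaluate(config, results)
    stage_rank(config)
    stage_rules(config)
    logger.info("pipeline done in %.1fs (seed=%d, config=%s)",
                time.time() - t0, config.seed, config.config_hash())
    return report
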