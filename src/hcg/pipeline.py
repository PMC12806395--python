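"""End-to-end orchestration: simulate/read -> preprocess -> balance ->
fit cascades -> evaluate -> survival -> strategy comparison -> markers.

This is the library behind the ``hcg`` command line; every stage is also
usable on its own.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import omics_io
from .clinical_eval import SurvivalReport, fit_multivariate_cox, rank_strategies
from .hierarchy import (CascadeModel, SplitTree, fit_cascade, predict_subtype,
                        predict_subtype_proba, strategy_catalog)
from .markers import alteration_rates, difference_tests
from .metrics import MetricsReport, evaluate_multiclass
from .omics_io import MODALITIES, OmicsCohort, scale_cohort
from .simulate import SimulationConfig, train_test_cohorts
from .sparse_linear import default_grid

logger = logging.getLogger(__name__)

MODALITY_CODES = {"G": ("mutation",), "C": ("cna",), "M": ("methylation",),
                  "A": ("mutation", "cna", "methylation")}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    strategies: tuple = ("I-MC", "II-HC", "III-HC")
    modalities: tuple = ("A",)          # subset of {G, C, M, A}
    n_train: int = 600
    n_test: int = 300
    n_genes: int = 1000
    smote_k: int = 5
    cv_folds: int = 5
    n_lambda: int = 6                   # grid points for lambda selection
    lambda_decades: float = 2.0
    marker_alpha: float = 1e-5
    reference_sex: str = "female"
    seed: int = 0
    custom_tree: Optional[str] = None   # path to a YAML SplitTree
    simulate: Optional[dict] = None     # overrides for SimulationConfig

    def __post_init__(self) -> None:
        if not self.modalities:
            raise ValueError("modalities must be non-empty")
        bad = set(self.modalities) - set(MODALITY_CODES)
        if bad:
            raise ValueError(f"unknown modality codes {sorted(bad)}")

    def config_hash(self) -> str:
        text = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("strategies", "modalities"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RunResult:
    """In-memory artifacts of one pipeline run."""

    config: RunConfig
    cascades: dict                      # (strategy, code) -> CascadeModel
    metrics: dict                       # (strategy, code) -> MetricsReport
    survival: dict                      # (strategy, code) -> SurvivalReport
    comparison: pd.DataFrame
    selected: str
    rates: pd.DataFrame
    markers: pd.DataFrame
    test_predictions: dict              # (strategy, code) -> pd.Series


def preprocess_cohorts(train: OmicsCohort, test: Optional[OmicsCohort] = None,
                       knn_k: int = 10) -> tuple[OmicsCohort, Optional[OmicsCohort], dict]:
    """Impute methylation and min-max scale, fitting scalers on train only."""
    meth = omics_io.impute_knn(train.methylation, k=knn_k)
    train = OmicsCohort(train.mutation, train.cna, meth, train.clinical,
                        train.labels)
    if test is not None:
        meth_t = omics_io.impute_knn(test.methylation, k=knn_k)
        # restrict both cohorts to genes that survived imputation in both
        genes = meth.genes.intersection(meth_t.genes)
        train = OmicsCohort(train.mutation, train.cna,
                            omics_io.GeneSampleMatrix(
                                meth.values.loc[genes], "methylation"),
                            train.clinical, train.labels)
        test = OmicsCohort(test.mutation, test.cna,
                           omics_io.GeneSampleMatrix(
                               meth_t.values.loc[genes], "methylation"),
                           test.clinical, test.labels)
    train_scaled, scalers = scale_cohort(train, train.samples)
    test_scaled = None
    if test is not None:
        mats = {m: omics_io.apply_scaler(test.matrix(m), scalers[m])
                for m in MODALITIES}
        test_scaled = OmicsCohort(mats["mutation"], mats["cna"],
                                  mats["methylation"], test.clinical,
                                  test.labels)
    return train_scaled, test_scaled, scalers


def get_strategies(names: Sequence[str],
                   custom_tree: Optional[str] = None) -> dict:
    catalog = strategy_catalog()
    out = {}
    for name in names:
        if name in catalog:
            out[name] = catalog[name]
        elif custom_tree is not None:
            tree = SplitTree.from_yaml(custom_tree)
            out[tree.name] = tree
        else:
            raise ValueError(f"unknown strategy {name!r}")
    return out


def run_pipeline(config: RunConfig,
                 train: Optional[OmicsCohort] = None,
                 test: Optional[OmicsCohort] = None) -> RunResult:
    """Run the full pipeline; cohorts are simulated unless provided."""
    cfg = config
    rng_seed = cfg.seed
    if train is None or test is None:
        sim_kwargs = dict(cfg.simulate or {})
        sim_kwargs.setdefault("n_samples", cfg.n_train)
        sim_kwargs.setdefault("n_genes", cfg.n_genes)
        sim_kwargs.setdefault("seed", rng_seed)
        sim_cfg = SimulationConfig(**sim_kwargs)
        train, test, _, _ = train_test_cohorts(sim_cfg, n_test=cfg.n_test)
        logger.info("simulated cohorts: train n=%d, test n=%d, %d genes/modality",
                    train.n_samples, test.n_samples, sim_cfg.n_genes)

    train_p, test_p, _ = preprocess_cohorts(train, test)
    full_train_features = train_p.feature_table()

    strategies = get_strategies(cfg.strategies, cfg.custom_tree)
    cascades, metrics, survival, predictions = {}, {}, {}, {}
    for code in cfg.modalities:
        mods = MODALITY_CODES[code]
        cols = [c for c in full_train_features.columns
                if c.split(":", 1)[0] in mods]
        X_train = full_train_features[cols]
        X_test = test_p.feature_table()[cols]
        grid = default_grid(X_train, train_p.labels, n_points=cfg.n_lambda,
                            decades=cfg.lambda_decades)
        for name, tree in strategies.items():
            key = f"{name}({code})"
            cascade = fit_cascade(X_train, train_p.labels, tree, grid=grid,
                                  folds=cfg.cv_folds, seed=rng_seed,
                                  smote_k=cfg.smote_k)
            proba = predict_subtype_proba(cascade, X_test)
            pred = predict_subtype(cascade, X_test)
            report = evaluate_multiclass(test_p.labels, proba, pred,
                                         classifier=key)
            clin = test_p.clinical.data
            surv = fit_multivariate_cox(pred, clin["age"], clin["sex"],
                                        clin["os_time"], clin["os_event"],
                                        reference_sex=cfg.reference_sex,
                                        classifier=key)
            cascades[key] = cascade
            metrics[key] = report
            survival[key] = surv
            predictions[key] = pred
            logger.info("%s: overall auROC=%.3f, stratification p=%.3g",
                        key, report.overall["auROC"], surv.overall_p)

    comparison = rank_strategies(survival, metrics)
    selected = comparison.index[comparison["selected"]][0]
    sel_pred = predictions[selected]
    # rates and marker tests run on the raw alteration values (the scaled
    # representation is for model fitting; a min-max-scaled CNA cell is
    # nonzero even for an unaltered gene)
    rates = alteration_rates(test, sel_pred)
    marker_table = difference_tests(
        test, sel_pred,
        feature_subset=cascades[selected].selected_features(),
        alpha=cfg.marker_alpha)
    return RunResult(config=cfg, cascades=cascades, metrics=metrics,
                     survival=survival, comparison=comparison,
                     selected=selected, rates=rates, markers=marker_table,
                     test_predictions=predictions)


def write_run(result: RunResult, out_dir) -> Path:
    """Write every artifact of a run, with config hash in each header."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = result.config.config_hash()
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump({"config_hash": chash, **asdict(result.config)}, fh,
                       sort_keys=False)
    for key, report in result.metrics.items():
        report.to_json(out / f"metrics_{key}.json")
    for key, surv in result.survival.items():
        surv.to_json(out / f"survival_{key}.json")
    comp = result.comparison.copy()
    comp.insert(0, "config_hash", chash)
    comp.to_csv(out / "comparison.tsv", sep="\t")
    rates = result.rates.copy()
    rates.insert(0, "config_hash", chash)
    rates.to_csv(out / "rates.tsv", sep="\t")
    result.markers.to_csv(out / "markers.tsv", sep="\t", index=False)
    with open(out / "selected.txt", "w") as fh:
        fh.write(result.selected + "\n")
    return out
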