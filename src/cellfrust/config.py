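"""End-to-end experiment configuration and driver.

A :class:`RunConfig` carries the data source (a labelled CSV or a synthetic
recipe) together with every algorithm parameter, each defaulting to its
standard value: tail-probability cap ``v_max`` = 5%, repertoire size
``N_pop`` = 12, connectivity ``C`` = 20, education window ``W_tau`` = 1e4
iterations, sample-change period ``T_S`` = 100, detection window ``W_d`` =
1e4, anergy time ``tau_A`` = 5 (activation duration equal to it),
calibration fraction ``f`` = 0.1 and operating ``FPR`` = 0.1.

``run_experiment`` executes Monte-Carlo cross-validation folds end-to-end
— split, feature replication, mapper fit, repertoire education,
calibration, scoring — with per-fold seeds derived from one master seed,
and aggregates TPR@FPR and ROC curves across folds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .datasets import (LabeledDataset, SemiSupervisedSplit, SyntheticConfig,
                       generate_synthetic, load_csv, monte_carlo_folds,
                       replicate_features, replication_factor)
from .detection import (DetectionParams, baseline_ilists_rare_count,
                        baseline_rare_count, calibrate, roc_curve,
                        score_samples, tpr_at_fpr)
from .core import build_population
from .signals import fit_mapper
from .training import Repertoire, TrainingParams, build_repertoire

__all__ = ["RunConfig", "run_experiment", "run_fold", "prepare_fold"]


@dataclass(frozen=True)
class RunConfig:
    # data source: either a CSV...
    csv_path: Optional[str] = None
    label_column: str = "label"
    normal_labels: tuple = ()
    n_train: int = 0
    # ...or a synthetic recipe
    synthetic: Optional[SyntheticConfig] = None
    # algorithm parameters (standard defaults)
    v_max: float = 0.05
    N_pop: int = 12
    C: int = 20
    W_tau: int = 10_000
    T_S: int = 100
    W_d: int = 10_000
    tau_A: int = 5
    tau_act: Optional[int] = None
    f: float = 0.1
    FPR: float = 0.1
    strategy: str = "AIS"
    t_max: int = 100
    tau_target: Optional[int] = None
    min_presenters: int = 32
    folds: int = 10
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.csv_path is None) == (self.synthetic is None):
            raise ValueError("configure exactly one of csv_path or synthetic")
        if self.csv_path is not None and not self.normal_labels:
            raise ValueError("CSV runs need a nonempty normal_labels set")
        object.__setattr__(self, "normal_labels", tuple(self.normal_labels))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        return cls(**raw)

    def training_params(self, seed: int) -> TrainingParams:
        return TrainingParams(strategy=self.strategy, W_tau=self.W_tau,
                              T_S=self.T_S, t_max=self.t_max,
                              tau_target=self.tau_target, seed=seed)

    def detection_params(self, seed: int) -> DetectionParams:
        return DetectionParams(W_d=self.W_d, tau_A=self.tau_A,
                               tau_act=self.tau_act, f=self.f,
                               FPR=self.FPR, seed=seed)


def _replicated_split(split: SemiSupervisedSplit,
                      min_presenters: int) -> tuple[SemiSupervisedSplit, np.ndarray]:
    """Replicate every part of a split and derive balanced presenter
    subtypes (alternating across replica blocks)."""
    nf = split.train_normal.n_features
    k = replication_factor(nf, min_presenters)
    parts = [replicate_features(p, min_presenters) if p is not None else None
             for p in (split.train_normal, split.test_normal, split.test_anomalous)]
    N = parts[0].n_features
    if k > 1:
        subtype = np.where((np.arange(N) // nf) % 2 == 0, 1, 2).astype(np.int64)
    else:
        if N % 2:
            raise ValueError("odd feature count without replication; "
                             "raise min_presenters")
        subtype = np.where(np.arange(N) % 2 == 0, 1, 2).astype(np.int64)
    return SemiSupervisedSplit(parts[0], parts[1], parts[2], split.seed), subtype


def prepare_fold(split: SemiSupervisedSplit, cfg: RunConfig, seed: int
                 ) -> Repertoire:
    """Replicate features, fit the mapper, build and educate a repertoire."""
    rsplit, subtype = _replicated_split(split, cfg.min_presenters)
    mapper = fit_mapper(rsplit.train_normal)
    ss = np.random.SeedSequence(seed)
    s_pop, s_train = (int(x) for x in ss.generate_state(2) % (2**31 - 1))
    pop = build_population(mapper, C=min(cfg.C, mapper.n_features),
                           v_max=cfg.v_max, seed=s_pop, subtype=subtype)
    Fv_train = mapper.cdf(rsplit.train_normal.X)
    rep = build_repertoire(pop, Fv_train, cfg.training_params(s_train),
                           n_pop=cfg.N_pop)
    return rep


def run_fold(split: SemiSupervisedSplit, cfg: RunConfig, seed: int) -> dict:
    """One fold end-to-end; returns scores, TPR@FPR and the ROC table."""
    rsplit, _ = _replicated_split(split, cfg.min_presenters)
    rep = prepare_fold(split, cfg, seed)
    ss = np.random.SeedSequence(seed + 1)
    s_cal, s_norm, s_anom = (int(x) for x in ss.generate_state(3) % (2**31 - 1))
    dparams = cfg.detection_params(s_cal)
    th = calibrate(rep, rsplit.train_normal.X, dparams)
    if rsplit.test_normal is None:
        raise ValueError("fold has no normal test samples to set the FPR")
    R_norm = score_samples(rep, rsplit.test_normal.X, th, dparams, s_norm)
    R_anom = score_samples(rep, rsplit.test_anomalous.X, th, dparams, s_anom)
    return {
        "tpr": tpr_at_fpr(R_norm, R_anom, cfg.FPR),
        "roc": roc_curve(R_norm, R_anom),
        "R_normal": R_norm,
        "R_anomalous": R_anom,
        "repertoire": rep,
        "split": rsplit,
        "traces": rep.traces,
    }


def _make_folds(cfg: RunConfig) -> list[SemiSupervisedSplit]:
    rng = np.random.default_rng(cfg.seed)
    fold_seeds = rng.integers(0, 2**31 - 1, size=cfg.folds)
    if cfg.csv_path is not None:
        ds = load_csv(cfg.csv_path, cfg.label_column)
        return monte_carlo_folds(ds, cfg.normal_labels, cfg.n_train,
                                 cfg.folds, cfg.seed)
    return [generate_synthetic(dataclasses.replace(cfg.synthetic, seed=int(s)))
            for s in fold_seeds]


def run_experiment(cfg: RunConfig) -> dict:
    """Monte-Carlo cross-validated end-to-end run.

    Returns per-fold TPR@FPR, their mean and standard deviation, the mean
    ROC curve with per-point standard deviations, and the per-fold
    training iteration counts.  If ``cfg.out_dir`` is set, response
    tables, the ROC table and a run log are written there as CSV/JSON.
    """
    folds = _make_folds(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    fold_seeds = rng.integers(0, 2**31 - 1, size=cfg.folds)
    results = [run_fold(split, cfg, int(s))
               for split, s in zip(folds, fold_seeds)]

    tprs = np.array([r["tpr"] for r in results])
    rocs = np.stack([r["roc"][:, 1] for r in results])
    roc_mean = np.column_stack([results[0]["roc"][:, 0],
                                rocs.mean(axis=0), rocs.std(axis=0)])
    iters = np.array([sum(tr["total_iters"] for tr in r["traces"])
                      for r in results])
    out = {
        "tpr_per_fold": tprs,
        "tpr_mean": float(tprs.mean()),
        "tpr_sd": float(tprs.std()),
        "roc_mean": roc_mean,
        "training_iters_per_fold": iters,
        "folds": results,
    }
    if cfg.out_dir is not None:
        _write_outputs(cfg, out)
    return out


def _write_outputs(cfg: RunConfig, out: dict) -> None:
    import pandas as pd

    d = Path(cfg.out_dir)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, r in enumerate(out["folds"]):
        for lab, scores in (("normal", r["R_normal"]),
                            ("anomalous", r["R_anomalous"])):
            for s, R in enumerate(scores):
                rows.append({"fold": k, "label": lab, "sample": s, "R": R})
    pd.DataFrame(rows).to_csv(d / "responses.csv", index=False)
    pd.DataFrame(out["roc_mean"], columns=["FPR", "TPR_mean", "TPR_sd"]) \
        .to_csv(d / "roc.csv", index=False)
    log = {
        "seed": cfg.seed,
        "tpr_per_fold": out["tpr_per_fold"].tolist(),
        "tpr_mean": out["tpr_mean"],
        "tpr_sd": out["tpr_sd"],
        "config": dataclasses.asdict(cfg),
    }
    with open(d / "run.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
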