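"""Nested cross-validation with random-search tuning, and metric reporting.

The outer loop is stratified group 5-fold (all samples of a subject share a
fold; label proportions preserved); hyperparameters are chosen per outer
fold by mean inner-CV validation accuracy, the winner retrained on the outer
training fold with an internal early-stopping holdout, and scored once on
the untouched outer test fold.  Any statistic used to transform inputs
(age standardization for the metadata vector) is computed on training
subjects only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedGroupKFold

from .cohort import Cohort
from .nn import ArchitectureConfig, TrainConfig, fit_dualpath
from .nn.train import accuracy as model_accuracy
from .preprocess import age_stats_from, encode_metadata


def metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """Accuracy, case-class and macro precision/recall, macro-F1.

    A class absent from ``y_true`` gets F1 = 0 with a warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if len(np.unique(y_true)) < 2:
        warnings.warn("a class is absent from y_true; its F1 is defined as 0")
    p, r, f, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=[0, 1], average=None, zero_division=0)
    return {
        "accuracy": float((y_true == y_pred).mean()),
        "precision_case": float(p[1]),
        "recall_case": float(r[1]),
        "precision_macro": float(p.mean()),
        "recall_macro": float(r.mean()),
        "macro_f1": float(f.mean()),
    }


def stratified_group_folds(labels: np.ndarray, subject_ids: np.ndarray,
                           k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold index per sample; subjects never straddle folds."""
    labels = np.asarray(labels)
    subject_ids = np.asarray(subject_ids)
    # one label per subject for the minority-class check
    subj_label = {s: l for s, l in zip(subject_ids, labels)}
    counts = np.bincount(np.fromiter(subj_label.values(), dtype=int), minlength=2)
    if k > counts.min():
        raise ValueError(f"k={k} exceeds minority-class subject count {counts.min()}")
    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.full(len(labels), -1, dtype=int)
    for f, (_, test_idx) in enumerate(splitter.split(labels, labels, groups=subject_ids)):
        folds[test_idx] = f
    return folds


@dataclass
class SearchSpace:
    """Random-search ranges for learning rate, batch size, dropout and the
    fusion weight alpha."""

    lr_range: tuple[float, float] = (3e-4, 1e-2)       # log-uniform
    batch_sizes: tuple[int, ...] = (8, 16, 32)
    dropout_range: tuple[float, float] = (0.2, 0.6)
    alpha_range: tuple[float, float] = (0.0, 1.0)
    n_samples: int = 3
    seed: int = 0

    def sample(self, rng: np.random.Generator) -> dict:
        lo, hi = np.log(self.lr_range[0]), np.log(self.lr_range[1])
        return {
            "lr": float(np.exp(rng.uniform(lo, hi))),
            "batch_size": int(rng.choice(self.batch_sizes)),
            "dropout": float(rng.uniform(*self.dropout_range)),
            "fusion_alpha": float(rng.uniform(*self.alpha_range)),
        }


@dataclass
class CvReport:
    fold_metrics: pd.DataFrame
    mean: dict[str, float]
    sd: dict[str, float]
    chosen: list[dict]
    fold_assignments: np.ndarray
    seeds: dict = field(default_factory=dict)


def prepare_inputs(cohort: Cohort, scale: str = "none") -> tuple[np.ndarray, np.ndarray]:
    """Stack a cohort into (N, R, T) float32 plus integer labels.

    ``scale='zscore'`` applies per-region z-scoring across time within each
    subject; the default leaves amplitudes intact so stable mean-offset
    signatures remain visible to the pooled branch.
    """
    X = np.stack([ts.data for ts in cohort.series]).astype(np.float32)
    if scale == "zscore":
        mu = X.mean(axis=2, keepdims=True)
        sd = X.std(axis=2, keepdims=True)
        sd[sd == 0] = 1
        X = (X - mu) / sd
    elif scale != "none":
        raise ValueError(f"unknown scale mode {scale!r}")
    return X, cohort.labels


def encode_cohort_metadata(cohort: Cohort, train_idx: np.ndarray,
                           site_levels: list[str] | None = None,
                           sex_levels: list[str] | None = None) -> np.ndarray:
    """Metadata matrix for all subjects with age statistics from train only."""
    records = cohort.records
    site_levels = site_levels or cohort.site_levels
    sex_levels = sex_levels or cohort.sex_levels
    stats = age_stats_from([records[i] for i in train_idx])
    return np.stack([
        encode_metadata(rec, site_levels, stats, sex_levels=sex_levels).values
        for rec in records
    ]).astype(np.float32)


def _train_eval(X, y, meta, arch, cfg, train_idx, val_idx):
    trained = fit_dualpath(X[train_idx], meta[train_idx], y[train_idx], arch, cfg,
                           X_val=X[val_idx], meta_val=meta[val_idx], y_val=y[val_idx])
    model = trained.build()
    return model_accuracy(model, X[val_idx], meta[val_idx], y[val_idx]), trained


def nested_cv(
    cohort: Cohort,
    space: SearchSpace,
    arch: ArchitectureConfig,
    k_outer: int = 5,
    k_inner: int = 3,
    train_cfg: TrainConfig | None = None,
    seed: int = 0,
    scale: str = "none",
) -> CvReport:
    """Nested CV: random search in the inner loop, untouched outer test."""
    base_cfg = train_cfg or TrainConfig()
    X, y = prepare_inputs(cohort, scale=scale)
    sids = np.array(cohort.subject_ids)
    folds = stratified_group_folds(y, sids, k=k_outer, seed=seed)
    rng = np.random.default_rng(space.seed)
    configs = [space.sample(rng) for _ in range(space.n_samples)]

    rows, chosen = [], []
    for f in range(k_outer):
        test_idx = np.flatnonzero(folds == f)
        outer_train = np.flatnonzero(folds != f)
        inner_folds = stratified_group_folds(
            y[outer_train], sids[outer_train], k=k_inner, seed=seed + 1000 + f)
        # inner loop: mean validation accuracy per candidate
        best_cfg, best_score = None, -1.0
        for cand in configs:
            arch_c = replace(arch, dropout=cand["dropout"],
                             fusion_alpha=cand["fusion_alpha"])
            cfg_c = replace(base_cfg, lr=cand["lr"], batch_size=cand["batch_size"],
                            seed=seed + f)
            accs = []
            for g in range(k_inner):
                val_rel = np.flatnonzero(inner_folds == g)
                tr_rel = np.flatnonzero(inner_folds != g)
                tr_idx, val_idx = outer_train[tr_rel], outer_train[val_rel]
                if len(np.unique(y[tr_idx])) < 2 or len(np.unique(y[val_idx])) < 2:
                    warnings.warn("degenerate inner fold; skipping")
                    continue
                meta = encode_cohort_metadata(cohort, tr_idx)
                acc, _ = _train_eval(X, y, meta, arch_c, cfg_c, tr_idx, val_idx)
                accs.append(acc)
            score = float(np.mean(accs)) if accs else -1.0
            if score > best_score:
                best_score, best_cfg = score, cand
        chosen.append({**best_cfg, "inner_score": best_score, "fold": f})

        # retrain the winner on the outer training fold (internal holdout
        # inside fit_dualpath handles early stopping), score on outer test
        arch_b = replace(arch, dropout=best_cfg["dropout"],
                         fusion_alpha=best_cfg["fusion_alpha"])
        cfg_b = replace(base_cfg, lr=best_cfg["lr"],
                        batch_size=best_cfg["batch_size"], seed=seed + 500 + f)
        meta = encode_cohort_metadata(cohort, outer_train)
        trained = fit_dualpath(X[outer_train], meta[outer_train], y[outer_train],
                               arch_b, cfg_b)
        model = trained.build()
        y_pred = model.predict(X[test_idx], meta[test_idx])
        row = metrics(y[test_idx], y_pred)
        row["fold"] = f
        rows.append(row)

    fold_df = pd.DataFrame(rows)
    metric_cols = [c for c in fold_df.columns if c != "fold"]
    return CvReport(
        fold_metrics=fold_df,
        mean={c: float(fold_df[c].mean()) for c in metric_cols},
        sd={c: float(fold_df[c].std(ddof=1)) for c in metric_cols},
        chosen=chosen,
        fold_assignments=folds,
        seeds={"split_seed": seed, "search_seed": space.seed},
    )


def cross_validate_fixed(
    cohort: Cohort,
    arch: ArchitectureConfig,
    train_cfg: TrainConfig,
    k: int = 5,
    seed: int = 0,
    scale: str = "none",
) -> CvReport:
    """Plain stratified-group k-fold CV with fixed hyperparameters."""
    X, y = prepare_inputs(cohort, scale=scale)
    sids = np.array(cohort.subject_ids)
    folds = stratified_group_folds(y, sids, k=k, seed=seed)
    rows = []
    for f in range(k):
        test_idx = np.flatnonzero(folds == f)
        train_idx = np.flatnonzero(folds != f)
        meta = encode_cohort_metadata(cohort, train_idx)
        cfg = replace(train_cfg, seed=seed + f)
        trained = fit_dualpath(X[train_idx], meta[train_idx], y[train_idx], arch, cfg)
        model = trained.build()
        row = metrics(y[test_idx], model.predict(X[test_idx], meta[test_idx]))
        row["fold"] = f
        rows.append(row)
    fold_df = pd.DataFrame(rows)
    metric_cols = [c for c in fold_df.columns if c != "fold"]
    return CvReport(fold_df,
                    {c: float(fold_df[c].mean()) for c in metric_cols},
                    {c: float(fold_df[c].std(ddof=1)) for c in metric_cols},
                    [], folds, {"split_seed": seed})


def repeated_cv(
    cohort: Cohort,
    arch: ArchitectureConfig,
    train_cfg: TrainConfig,
    n_repeats: int = 100,
    k: int = 5,
    base_seed: int = 0,
    scale: str = "none",
) -> pd.DataFrame:
    """Repeat k-fold CV with distinct split seeds; per-repeat mean metrics."""
    rows = []
    for rep in range(n_repeats):
        report = cross_validate_fixed(cohort, arch, train_cfg, k=k,
                                      seed=base_seed + 7919 * rep, scale=scale)
        rows.append({"repeat": rep, **report.mean})
    return pd.DataFrame(rows)
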