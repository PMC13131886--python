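"""Mini-batch training with early stopping on held-out accuracy."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import cross_entropy
from .model import ArchitectureConfig, DualPathClassifier, TrainedDualPath, predict_labels
from .optim import Adam


@dataclass
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 100
    patience: int = 10
    min_epochs: int = 10  # early stopping cannot fire before this epoch:
                          # slow-starting runs sit at chance for a few epochs
                          # and a small holdout makes accuracy too noisy there
    seed: int = 0
    holdout_frac: float = 0.1   # internal early-stopping split when no val set given


def _stratified_holdout(y: np.ndarray, frac: float,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Stratified index split; every class keeps at least one holdout sample."""
    hold = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_hold = max(1, int(round(frac * len(idx))))
        hold.extend(idx[:n_hold])
    hold = np.sort(np.array(hold))
    train = np.setdiff1d(np.arange(len(y)), hold)
    return train, hold


def accuracy(model: DualPathClassifier, X: np.ndarray, meta: np.ndarray,
             y: np.ndarray, batch: int = 64) -> float:
    preds = []
    for i in range(0, len(y), batch):
        preds.append(model.predict(X[i:i + batch], meta[i:i + batch]))
    return float((np.concatenate(preds) == y).mean())


def fit_dualpath(
    X: np.ndarray,
    meta: np.ndarray,
    y: np.ndarray,
    arch: ArchitectureConfig,
    cfg: TrainConfig,
    X_val: np.ndarray | None = None,
    meta_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> TrainedDualPath:
    """Train with Adam on cross-entropy; restore the best-validation state.

    One integer seed controls initialization, dropout masks, the internal
    holdout split and batch order.
    """
    rng = np.random.default_rng(cfg.seed)
    if X_val is None:
        tr_idx, ho_idx = _stratified_holdout(y, cfg.holdout_frac, rng)
        X_val, meta_val, y_val = X[ho_idx], meta[ho_idx], y[ho_idx]
        X, meta, y = X[tr_idx], meta[tr_idx], y[tr_idx]

    model = DualPathClassifier(arch, seed=cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    n = len(y)
    best_acc, best_state, best_epoch = -1.0, model.state_dict(), 0
    bad = 0
    history = []
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        ep_loss = 0.0
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            if len(idx) < 2:
                continue  # batch-norm needs at least two samples
            model.zero_grad()
            out = model.forward(X[idx], meta[idx], train=True, rng=rng)
            loss, dlogits = cross_entropy(out["fused"], y[idx])
            model.backward(dfused=dlogits)
            opt.step(model.gradients())
            ep_loss += loss * len(idx)
        val_acc = accuracy(model, X_val, meta_val, y_val)
        history.append({"epoch": epoch, "loss": ep_loss / n, "val_acc": val_acc})
        if val_acc > best_acc:
            best_acc, best_state, best_epoch = val_acc, model.state_dict(), epoch
            bad = 0
        else:
            bad += 1
            if bad >= cfg.patience and epoch >= cfg.min_epochs:
                break
    model.load_state_dict(best_state)
    return TrainedDualPath(
        architecture=arch,
        state=best_state,
        provenance={
            "seed": cfg.seed,
            "epochs_run": len(history),
            "early_stop_epoch": best_epoch,
            "best_val_acc": best_acc,
            "lr": cfg.lr,
            "batch_size": cfg.batch_size,
            "history": history,
        },
    )


def fit_ensemble(
    X: np.ndarray,
    meta: np.ndarray,
    y: np.ndarray,
    arch: ArchitectureConfig,
    cfg: TrainConfig,
    n_models: int = 4,
) -> list[TrainedDualPath]:
    """Train ``n_models`` networks differing only in seed.

    Independently seeded fits spread representation across redundant
    discriminative signals; attribution maps averaged over the ensemble are
    far more stable than any single fit's.
    """
    from dataclasses import replace
    return [fit_dualpath(X, meta, y, arch, replace(cfg, seed=cfg.seed + 101 * i))
            for i in range(n_models)]
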