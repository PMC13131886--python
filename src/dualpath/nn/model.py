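"""The dual-branch classifier.

A shared three-block temporal-convolution backbone (kernels 7, 7, 5, each
block conv -> batch-norm -> ReLU -> dropout, time length preserved) feeds
two branches: a global temporal-pooling branch that averages features over
time (permutation-invariant, trait-like), and an attention-based
multiple-instance-learning branch that aggregates timepoints with learned
frame-wise weights (event-sensitive).  Demographic/site metadata is
concatenated to both branch representations before their linear heads, and
the two branches' logits are fused by a convex weight alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .layers import (DTYPE, BatchNorm1d, Conv1d, Dropout, GatedAttention,
                     Layer, Linear, ReLU, cross_entropy, softmax)


@dataclass
class ArchitectureConfig:
    in_regions: int = 246
    conv_channels: tuple[int, int, int] = (128, 64, 64)
    kernel_sizes: tuple[int, int, int] = (7, 7, 5)
    dropout: float = 0.5
    attention_hidden: int = 64
    metadata_dim: int = 6          # sex(2) + site(3) + age(1)
    n_classes: int = 2
    fusion_alpha: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if not 0 <= self.fusion_alpha <= 1:
            raise ValueError("fusion_alpha must be in [0, 1]")
        if len(self.conv_channels) != 3 or len(self.kernel_sizes) != 3:
            raise ValueError("three conv blocks expected")


def fuse(global_logits: np.ndarray, mil_logits: np.ndarray, alpha: float) -> np.ndarray:
    """Convex logit fusion: alpha * global + (1 - alpha) * MIL."""
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    return alpha * global_logits + (1 - alpha) * mil_logits


def predict_labels(fused_logits: np.ndarray) -> np.ndarray:
    """Argmax with ties broken to class 0 (np.argmax takes the first max)."""
    return np.argmax(fused_logits, axis=1)


class DualPathClassifier:
    """Forward/backward passes for both branches, with input gradients."""

    def __init__(self, config: ArchitectureConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c1, c2, c3 = config.conv_channels
        k1, k2, k3 = config.kernel_sizes
        p = config.dropout
        self.backbone: list[Layer] = [
            Conv1d(config.in_regions, c1, k1, rng), BatchNorm1d(c1), ReLU(), Dropout(p),
            Conv1d(c1, c2, k2, rng), BatchNorm1d(c2), ReLU(), Dropout(p),
            Conv1d(c2, c3, k3, rng), BatchNorm1d(c3), ReLU(), Dropout(p),
        ]
        d = c3 + config.metadata_dim
        self.attention = GatedAttention(c3, config.attention_hidden, rng)
        self.global_head = Linear(d, config.n_classes, rng)
        self.mil_head = Linear(d, config.n_classes, rng)
        self._layers: dict[str, Layer] = {}
        for i, lyr in enumerate(self.backbone):
            self._layers[f"backbone.{i}"] = lyr
        self._layers["attention"] = self.attention
        self._layers["global_head"] = self.global_head
        self._layers["mil_head"] = self.mil_head

    # -- parameter access ---------------------------------------------------
    def parameters(self) -> dict[str, np.ndarray]:
        return {f"{ln}.{pn}": arr for ln, lyr in self._layers.items()
                for pn, arr in lyr.params.items()}

    def gradients(self) -> dict[str, np.ndarray]:
        return {f"{ln}.{pn}": arr for ln, lyr in self._layers.items()
                for pn, arr in lyr.grads.items()}

    def zero_grad(self) -> None:
        for lyr in self._layers.values():
            lyr.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.copy() for k, v in self.parameters().items()}
        for ln, lyr in self._layers.items():
            if isinstance(lyr, BatchNorm1d):
                state[f"{ln}.running_mean"] = lyr.running_mean.copy()
                state[f"{ln}.running_var"] = lyr.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for ln, lyr in self._layers.items():
            for pn in lyr.params:
                lyr.params[pn][...] = state[f"{ln}.{pn}"]
            if isinstance(lyr, BatchNorm1d):
                lyr.running_mean[...] = state[f"{ln}.running_mean"]
                lyr.running_var[...] = state[f"{ln}.running_var"]

    # -- forward / backward -------------------------------------------------
    def backbone_forward(self, x: np.ndarray, train: bool = False,
                         rng: np.random.Generator | None = None) -> np.ndarray:
        min_t = max(self.config.kernel_sizes)
        if x.shape[2] < min_t:
            raise ValueError(f"T={x.shape[2]} below minimum window {min_t}")
        h = np.asarray(x, dtype=DTYPE)
        for lyr in self.backbone:
            h = lyr.forward(h, train=train, rng=rng)
        return h

    def forward(self, x: np.ndarray, metadata: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> dict[str, np.ndarray]:
        meta = np.asarray(metadata, dtype=DTYPE)
        h = self.backbone_forward(x, train=train, rng=rng)
        self._h = h
        self._T = h.shape[2]
        pooled = h.mean(axis=2)
        self._cat_g = np.concatenate([pooled, meta], axis=1)
        g_logits = self.global_head.forward(self._cat_g, train=train)
        bag, attn = self.attention.forward(h, train=train)
        self._cat_m = np.concatenate([bag, meta], axis=1)
        m_logits = self.mil_head.forward(self._cat_m, train=train)
        fused = fuse(g_logits, m_logits, self.config.fusion_alpha)
        return {"fused": fused, "global": g_logits, "mil": m_logits,
                "attention": attn}

    def heads_forward(self, h: np.ndarray, metadata: np.ndarray) -> dict[str, np.ndarray]:
        """Branch outputs from given backbone features (B, C3, T).

        Useful for feature-level contracts: the global branch is invariant
        to any permutation of the feature columns, the MIL branch is not.
        """
        meta = np.asarray(metadata, dtype=DTYPE)
        pooled = h.mean(axis=2)
        g_logits = self.global_head.forward(np.concatenate([pooled, meta], axis=1))
        bag, attn = self.attention.forward(h)
        m_logits = self.mil_head.forward(np.concatenate([bag, meta], axis=1))
        return {"fused": fuse(g_logits, m_logits, self.config.fusion_alpha),
                "global": g_logits, "mil": m_logits, "attention": attn}

    def backward(self, dfused: np.ndarray | None = None,
                 dglobal: np.ndarray | None = None,
                 dmil: np.ndarray | None = None) -> np.ndarray:
        """Backpropagate branch-logit gradients; returns d(input)."""
        a = self.config.fusion_alpha
        c3 = self.config.conv_channels[2]
        dg = np.zeros((self._cat_g.shape[0], self.config.n_classes), dtype=DTYPE)
        dm = dg.copy()
        if dfused is not None:
            dg += a * dfused.astype(DTYPE)
            dm += (1 - a) * dfused.astype(DTYPE)
        if dglobal is not None:
            dg += dglobal.astype(DTYPE)
        if dmil is not None:
            dm += dmil.astype(DTYPE)
        dcat_g = self.global_head.backward(dg)
        dpooled = dcat_g[:, :c3]
        dh = np.repeat(dpooled[:, :, None] / self._T, self._T, axis=2).astype(DTYPE)
        dcat_m = self.mil_head.backward(dm)
        dh += self.attention.backward(dcat_m[:, :c3])
        for lyr in reversed(self.backbone):
            dh = lyr.backward(dh)
        return dh

    # -- convenience --------------------------------------------------------
    def predict_proba(self, x: np.ndarray, metadata: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, metadata)["fused"])

    def predict(self, x: np.ndarray, metadata: np.ndarray) -> np.ndarray:
        return predict_labels(self.forward(x, metadata)["fused"])

    def input_gradient(self, x: np.ndarray, metadata: np.ndarray,
                       target: int, branch: str = "fused") -> np.ndarray:
        """Gradient of the target-class logit of one branch w.r.t. the input."""
        out = self.forward(x, metadata, train=False)
        sel = np.zeros_like(out["fused"])
        sel[:, target] = 1.0
        self.zero_grad()
        if branch == "fused":
            return self.backward(dfused=sel)
        if branch == "global":
            return self.backward(dglobal=sel)
        if branch == "mil":
            return self.backward(dmil=sel)
        raise ValueError(f"unknown branch {branch!r}")


@dataclass
class TrainedDualPath:
    """Fitted model plus architecture and training provenance."""

    architecture: ArchitectureConfig
    state: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)

    def build(self) -> DualPathClassifier:
        model = DualPathClassifier(self.architecture,
                                   seed=self.provenance.get("seed", 0))
        model.load_state_dict(self.state)
        return model

    def architecture_json(self) -> dict:
        return asdict(self.architecture)


loss = cross_entropy
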