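"""Cluster classifier (residual blocks + softmax) and domain discriminator.

The classifier maps the fused embedding h to region probabilities through
a stack of residual blocks, ``ResBlock(h) = h + ReLU(BN(W h))``, and a
final linear layer with row softmax; it is trained with cross-entropy on
the labeled source slice only.  An MLP variant (plain dense ReLU layers,
no skip/BN) is provided as an ablation with the same I/O contract.

The discriminator is a small feed-forward net with a single sigmoid unit
scoring whether an embedding came from the source (1) or target (0)
slice; its binary cross-entropy and the target encoder's reverse
objective are the two adversarial losses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

LOG_CLAMP = 1e-12  # floor inside every log for numerical safety


@dataclass
class ClassifierConfig:
    n_classes: int
    width: int = 64  # must equal the embedding width
    n_blocks: int = 2
    bn_momentum: float = 0.1
    bn_eps: float = 1e-5
    variant: str = "residual"  # or "mlp"

    def __post_init__(self):
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.variant not in ("residual", "mlp"):
            raise ValueError(f"unknown classifier variant {self.variant!r}")


@dataclass
class DiscriminatorConfig:
    input_dim: int = 64
    hidden: tuple[int, ...] = (64, 32)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class ClassifierState:
    """Residual/MLP classifier parameters plus batch-norm running state."""

    def __init__(self, cfg: ClassifierConfig, rng: np.random.Generator):
        self.cfg = cfg
        w = cfg.width
        p: dict[str, Tensor] = {}
        for i in range(cfg.n_blocks):
            p[f"block{i}/W"] = Tensor(_glorot(rng, w, w), requires_grad=True)
            if cfg.variant == "residual":
                p[f"block{i}/gamma"] = Tensor(np.ones(w), requires_grad=True)
                p[f"block{i}/beta"] = Tensor(np.zeros(w), requires_grad=True)
            else:
                p[f"block{i}/b"] = Tensor(np.zeros(w), requires_grad=True)
        p["out/W"] = Tensor(_glorot(rng, w, cfg.n_classes), requires_grad=True)
        p["out/b"] = Tensor(np.zeros(cfg.n_classes), requires_grad=True)
        self.params = p
        # running BN statistics (plain arrays, not learned)
        self.running_mean = [np.zeros(w) for _ in range(cfg.n_blocks)]
        self.running_var = [np.ones(w) for _ in range(cfg.n_blocks)]
        self.bn_initialized = False

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {k: v.data.copy() for k, v in self.params.items()}
        for i in range(self.cfg.n_blocks):
            out[f"block{i}/running_mean"] = self.running_mean[i].copy()
            out[f"block{i}/running_var"] = self.running_var[i].copy()
        out["bn_initialized"] = np.array(float(self.bn_initialized))
        return out

    def load_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = np.array(arrays[k], dtype=np.float64)
        for i in range(self.cfg.n_blocks):
            self.running_mean[i] = np.array(arrays[f"block{i}/running_mean"])
            self.running_var[i] = np.array(arrays[f"block{i}/running_var"])
        self.bn_initialized = bool(arrays["bn_initialized"])


def _batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    state: ClassifierState,
    block: int,
    mode: str,
) -> Tensor:
    cfg = state.cfg
    if mode == "train":
        mu = x.mean(axis=0, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
        m = cfg.bn_momentum
        state.running_mean[block] = (1 - m) * state.running_mean[block] + m * mu.data.ravel()
        state.running_var[block] = (1 - m) * state.running_var[block] + m * var.data.ravel()
        x_hat = (x - mu) / ((var + cfg.bn_eps) ** 0.5)
    elif mode == "eval":
        if not state.bn_initialized:
            raise RuntimeError("eval-mode batch norm before any training step")
        mu = Tensor(state.running_mean[block][None, :])
        var = Tensor(state.running_var[block][None, :])
        x_hat = (x - mu) / ((var + cfg.bn_eps) ** 0.5)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return gamma * x_hat + beta


def residual_block(h: Tensor, state: ClassifierState, block: int, mode: str) -> Tensor:
    """h + ReLU(BN(W h)); batch statistics in train mode, running in eval."""
    p = state.params
    lin = h @ p[f"block{block}/W"]
    bn = _batch_norm(lin, p[f"block{block}/gamma"], p[f"block{block}/beta"], state, block, mode)
    return h + bn.relu()


def _softmax_rows(logits: Tensor) -> Tensor:
    shift = Tensor(logits.data.max(axis=1, keepdims=True))  # constant shift
    e = (logits - shift).exp()
    return e / e.sum(axis=1, keepdims=True)


def classifier_logits(h: Tensor, state: ClassifierState, mode: str = "eval") -> Tensor:
    p = state.params
    x = h
    for i in range(state.cfg.n_blocks):
        if state.cfg.variant == "residual":
            x = residual_block(x, state, i, mode)
        else:
            x = (x @ p[f"block{i}/W"] + p[f"block{i}/b"]).relu()
    if mode == "train":
        state.bn_initialized = True
    return x @ p["out/W"] + p["out/b"]


def classify(h: Tensor, state: ClassifierState, mode: str = "eval") -> Tensor:
    """Row-stochastic class probabilities softmax(ResDecoder(h))."""
    return _softmax_rows(classifier_logits(h, state, mode))


def cross_entropy_loss(y_hat: Tensor, y_onehot: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of the true classes (natural log)."""
    y = np.asarray(y_onehot, dtype=float)
    if y.shape != y_hat.data.shape:
        raise ValueError("prediction and one-hot label shapes differ")
    n = y.shape[0]
    return -(Tensor(y) * y_hat.clip_min(LOG_CLAMP).log()).sum() * (1.0 / n)


class DiscriminatorState:
    """Feed-forward domain discriminator ending in one sigmoid unit."""

    def __init__(self, cfg: DiscriminatorConfig, rng: np.random.Generator):
        self.cfg = cfg
        dims = (cfg.input_dim, *cfg.hidden, 1)
        p: dict[str, Tensor] = {}
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            p[f"layer{i}/W"] = Tensor(_glorot(rng, a, b), requires_grad=True)
            p[f"layer{i}/b"] = Tensor(np.zeros(b), requires_grad=True)
        self.params = p
        self.n_layers = len(dims) - 1

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = np.array(arrays[k], dtype=np.float64)


def discriminate(h: Tensor, state: DiscriminatorState) -> Tensor:
    """Per-row probability in (0,1) that the embedding is from the source."""
    x = h
    for i in range(state.n_layers - 1):
        x = (x @ state.params[f"layer{i}/W"] + state.params[f"layer{i}/b"]).relu()
    i = state.n_layers - 1
    return (x @ state.params[f"layer{i}/W"] + state.params[f"layer{i}/b"]).sigmoid()


def discriminator_loss(d_s: Tensor, d_t: Tensor) -> Tensor:
    """L_D = -E[log D(h_s)] - E[log(1 - D(h_t))]."""
    if d_s.data.size == 0 or d_t.data.size == 0:
        raise ValueError("both domains must contribute embeddings")
    return (
        -(d_s.clip_min(LOG_CLAMP).log()).mean()
        - ((1.0 - d_t).clip_min(LOG_CLAMP).log()).mean()
    )


def generator_loss(d_t: Tensor) -> Tensor:
    """L_G = -E[log D(h_t)] — the non-saturating reverse objective."""
    if d_t.data.size == 0:
        raise ValueError("need target embeddings")
    return -(d_t.clip_min(LOG_CLAMP).log()).mean()
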