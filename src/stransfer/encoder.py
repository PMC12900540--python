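"""Dual-graph variational GCN encoder with per-spot attention fusion.

Expression is first linearly embedded, then passed through two parallel
3-layer GCN branches — one propagating over the KNN graph, one over the
PPMI graph — each emitting a deterministic feature ``f_G`` plus Gaussian
posterior parameters ``mu_G, log sigma^2_G`` from which a latent ``z_G``
is drawn by the reparameterization trick (``z = mu + sigma * eps``).
A learned per-spot softmax attention weight fuses each pair across the
two branches:

    f = alpha_f * f_A + (1 - alpha_f) * f_P
    z = alpha_z * z_A + (1 - alpha_z) * z_P

and the unified embedding is the concatenation ``h = [f, z]``.

Layer layout per branch: two shared hidden GCN layers with ReLU, then
three parallel GCN output heads at depth three — ReLU for f, linear for
mu and log-variance.  An equivalent reading places f as the layer-3 ReLU
output with mu/log-variance as two extra parallel heads of the same
depth; the two are the same computation.  The GCN step itself is the
standard symmetric-normalized propagation ``sigma(G_hat @ H @ W)``.

No KL or reconstruction penalty is applied by default: the classifier
and adversarial losses are the only training signals, and the stochastic
sampling acts as regularization.  A standard Gaussian KL is available
behind ``kl_weight`` for experimentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat

BRANCHES = ("A", "P")


@dataclass
class EncoderConfig:
    input_dim: int = 60
    embed_dim: int = 128
    gcn_dims: tuple[int, int, int] = (64, 32, 32)  # trunk, trunk, heads
    activation: str = "relu"

    def __post_init__(self):
        if self.input_dim < 1 or self.embed_dim < 1 or any(d < 1 for d in self.gcn_dims):
            raise ValueError("all dimensions must be >= 1")
        if len(self.gcn_dims) != 3:
            raise ValueError("each branch has exactly three GCN layers")

    @property
    def latent_dim(self) -> int:
        return self.gcn_dims[-1]

    @property
    def h_dim(self) -> int:
        return 2 * self.latent_dim


@dataclass
class LatentBatch:
    """One forward pass: branch outputs, fusion weights, fused embedding."""

    E: Tensor
    f_branch: dict[str, Tensor]
    mu_branch: dict[str, Tensor]
    logvar_branch: dict[str, Tensor]
    z_branch: dict[str, Tensor]
    f: Tensor
    z: Tensor
    h: Tensor
    alpha_f: Tensor | None  # None in single-graph ablations
    alpha_z: Tensor | None


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class EncoderState:
    """All encoder parameters, addressable by name for checkpointing."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        d1, d2, d3 = cfg.gcn_dims
        p: dict[str, Tensor] = {}
        p["W_e"] = Tensor(_glorot(rng, cfg.input_dim, cfg.embed_dim), requires_grad=True)
        p["b_e"] = Tensor(np.zeros(cfg.embed_dim), requires_grad=True)
        for br in BRANCHES:
            p[f"{br}/W1"] = Tensor(_glorot(rng, cfg.embed_dim, d1), requires_grad=True)
            p[f"{br}/W2"] = Tensor(_glorot(rng, d1, d2), requires_grad=True)
            for head in ("f", "mu", "logvar"):
                p[f"{br}/W_{head}"] = Tensor(_glorot(rng, d2, d3), requires_grad=True)
        for fuser in ("f", "z"):
            p[f"att/w_{fuser}"] = Tensor(_glorot(rng, d3, 1), requires_grad=True)
            p[f"att/b_{fuser}"] = Tensor(np.zeros(1), requires_grad=True)
        self.params = p

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def copy(self) -> "EncoderState":
        new = object.__new__(EncoderState)
        new.cfg = self.cfg
        new.params = {
            k: Tensor(v.data.copy(), requires_grad=True) for k, v in self.params.items()
        }
        return new

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = np.array(arrays[k], dtype=np.float64)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def linear_embed(X: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """E = X @ W + b — the input projection to the embedding space."""
    return X @ W + b


def gcn_layer(H: Tensor, G_hat: Tensor, W: Tensor, activation: str = "relu") -> Tensor:
    """One graph convolution: sigma(G_hat @ H @ W)."""
    out = G_hat @ H @ W
    if activation == "relu":
        return out.relu()
    if activation in ("linear", "identity", None):
        return out
    raise ValueError(f"unknown activation {activation!r}")


def encode_branch(
    E: Tensor, G_hat: Tensor, state: EncoderState, branch: str
) -> tuple[Tensor, Tensor, Tensor]:
    """Three GCN layers of one branch -> (f, mu, log sigma^2)."""
    p = state.params
    h1 = gcn_layer(E, G_hat, p[f"{branch}/W1"], "relu")
    h2 = gcn_layer(h1, G_hat, p[f"{branch}/W2"], "relu")
    f = gcn_layer(h2, G_hat, p[f"{branch}/W_f"], "relu")
    mu = gcn_layer(h2, G_hat, p[f"{branch}/W_mu"], "linear")
    logvar = gcn_layer(h2, G_hat, p[f"{branch}/W_logvar"], "linear")
    return f, mu, logvar


def reparameterize(mu: Tensor, logvar: Tensor, eps: np.ndarray) -> Tensor:
    """z = mu + sigma * eps with sigma = exp(logvar / 2); eps is fixed input."""
    if eps.shape != mu.data.shape:
        raise ValueError("eps shape must match mu")
    return mu + (logvar * 0.5).exp() * Tensor(eps)


def attention_fuse(
    uA: Tensor, uP: Tensor, w: Tensor, b: Tensor
) -> tuple[Tensor, Tensor]:
    """Per-spot two-way softmax fusion; returns (fused, alpha_A).

    alpha = softmax over the scores (w' u_A + b, w' u_P + b), taken at the
    A coordinate — computed as sigmoid of the score difference, which is
    the same quantity in a numerically stable form.
    """
    if uA.data.shape != uP.data.shape:
        raise ValueError("branch features must have equal shape")
    score_a = uA @ w + b
    score_p = uP @ w + b
    alpha = (score_a - score_p).sigmoid()  # N x 1
    fused = alpha * uA + (1.0 - alpha) * uP
    return fused, alpha


def encode(
    X: Tensor | np.ndarray,
    G_hat_A: np.ndarray | None,
    G_hat_P: np.ndarray | None,
    state: EncoderState,
    eps: dict[str, np.ndarray] | None = None,
    graph_mode: str = "both",
) -> LatentBatch:
    """Full encoder forward pass producing the fused embedding h = [f, z].

    `eps` maps branch name to a fixed standard-normal draw (N x latent);
    None means eps = 0, i.e. the deterministic posterior-mean pass used at
    prediction time.  In single-graph modes the attention fuser is skipped
    and h is that branch's [f_G, z_G].
    """
    if graph_mode not in ("both", "knn", "ppmi"):
        raise ValueError(f"unknown graph_mode {graph_mode!r}")
    X = X if isinstance(X, Tensor) else Tensor(X)
    p = state.params
    E = linear_embed(X, p["W_e"], p["b_e"])
    n = X.data.shape[0]
    lat = state.cfg.latent_dim

    g_hats = {"A": G_hat_A, "P": G_hat_P}
    active = {"both": ("A", "P"), "knn": ("A",), "ppmi": ("P",)}[graph_mode]
    f_b, mu_b, lv_b, z_b = {}, {}, {}, {}
    for br in active:
        if g_hats[br] is None:
            raise ValueError(f"graph_mode {graph_mode!r} needs the {br} propagation matrix")
        g = Tensor(g_hats[br])
        f_b[br], mu_b[br], lv_b[br] = encode_branch(E, g, state, br)
        e = eps.get(br) if eps else None
        e = e if e is not None else np.zeros((n, lat))
        z_b[br] = reparameterize(mu_b[br], lv_b[br], e)

    if graph_mode == "both":
        f, alpha_f = attention_fuse(f_b["A"], f_b["P"], p["att/w_f"], p["att/b_f"])
        z, alpha_z = attention_fuse(z_b["A"], z_b["P"], p["att/w_z"], p["att/b_z"])
    else:
        (br,) = active
        f, z = f_b[br], z_b[br]
        alpha_f = alpha_z = None

    h = concat([f, z], axis=1)
    return LatentBatch(
        E=E, f_branch=f_b, mu_branch=mu_b, logvar_branch=lv_b, z_branch=z_b,
        f=f, z=z, h=h, alpha_f=alpha_f, alpha_z=alpha_z,
    )


def kl_divergence(batch: LatentBatch) -> Tensor:
    """Mean standard-Gaussian KL over the active branches (optional term)."""
    terms = []
    for br, mu in batch.mu_branch.items():
        lv = batch.logvar_branch[br]
        terms.append((-0.5 * (1.0 + lv - mu * mu - lv.exp())).mean())
    out = terms[0]
    for t in terms[1:]:
        out = out + t
    return out * (1.0 / len(terms))


def sample_eps(
    rng: np.random.Generator, n: int, latent_dim: int, graph_mode: str = "both"
) -> dict[str, np.ndarray]:
    """Fresh standard-normal draws for each active branch."""
    active = {"both": ("A", "P"), "knn": ("A",), "ppmi": ("P",)}[graph_mode]
    return {br: rng.standard_normal((n, latent_dim)) for br in active}
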