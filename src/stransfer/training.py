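"""Two-phase training: supervised source fit, then adversarial adaptation.

Phase 1 jointly optimizes the source encoder and the cluster classifier
by full-batch cross-entropy on the labeled source slice.

Phase 2 is ADDA-style: the target encoder starts as a copy of the trained
source encoder; the source encoder and classifier are then frozen while a
domain discriminator and the target encoder are updated in alternation —
the discriminator to tell source embeddings from target embeddings, the
target encoder to fool it.  At equilibrium the discriminator is reduced
to guessing (accuracy near 0.5 on held-out embeddings) and the source
classifier reads the aligned target embeddings directly, transferring the
source's region names to the target spots.

Everything is full batch (a slice of up to ~10^4 spots fits comfortably
in memory) and fully seeded: one seed fixes initialization, every
reparameterization draw and the held-out split, so identical configs give
bit-identical results on one machine.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, gather_rows
from .encoder import EncoderConfig, EncoderState, encode, kl_divergence, sample_eps
from .graphs import SpatialGraph, WalkConfig, build_spatial_graph
from .heads import (
    ClassifierConfig,
    ClassifierState,
    DiscriminatorConfig,
    DiscriminatorState,
    classify,
    cross_entropy_loss,
    discriminate,
    discriminator_loss,
    generator_loss,
)
from .io_preprocess import PreprocessConfig, PreprocessState, STSlice, align_genes, preprocess_expression
from .optim import Adam
from . import evaluation


@dataclass
class TrainConfig:
    seed: int = 0
    source_epochs: int = 200
    adapt_iters: int = 600  # cap only; the domain-accuracy band stops earlier
    d_steps: int = 1
    g_steps: int = 2
    lr_source: float = 1e-3
    lr_disc: float = 3e-4
    lr_target: float = 1e-4
    graph_mode: str = "both"  # "knn" | "ppmi" | "both"
    classifier_variant: str = "residual"  # or "mlp"
    adaptation: bool = True
    plateau_patience: int = 20  # source-phase early stop
    plateau_tol: float = 1e-4
    domain_band: tuple[float, float] = (0.45, 0.55)  # adaptation early stop
    band_patience: int = 20
    band_warmup: int = 100  # iterations before the band rule may fire
    holdout_frac: float = 0.2  # spots held out of adversarial updates
    kl_weight: float = 0.0
    divergence_factor: float = 10.0

    def __post_init__(self):
        if self.source_epochs < 1:
            raise ValueError("source_epochs must be >= 1")
        if self.adaptation and (self.adapt_iters < 1 or self.d_steps < 1 or self.g_steps < 1):
            raise ValueError("adaptation counts must be >= 1 when adaptation is on")
        if self.graph_mode not in ("knn", "ppmi", "both"):
            raise ValueError(f"unknown graph_mode {self.graph_mode!r}")


@dataclass
class TransferResult:
    predicted_labels: np.ndarray
    probabilities: np.ndarray
    class_names: list[str]
    spot_ids: np.ndarray
    source_embeddings: np.ndarray
    target_embeddings: np.ndarray
    history: dict[str, list[float]]
    metrics: dict | None
    config: dict


def _propagation(graph: SpatialGraph, mode: str):
    g_a = graph.knn_norm if mode in ("knn", "both") else None
    g_p = graph.ppmi_norm if mode in ("ppmi", "both") else None
    return g_a, g_p


def _one_hot(labels: np.ndarray, class_names: list[str]) -> tuple[np.ndarray, np.ndarray]:
    index = {c: i for i, c in enumerate(class_names)}
    y_idx = np.array([index[str(l)] for l in labels])
    y = np.zeros((len(labels), len(class_names)))
    y[np.arange(len(labels)), y_idx] = 1.0
    return y, y_idx


# ---------------------------------------------------------------------------
# phase 1: supervised source training
# ---------------------------------------------------------------------------

def train_source(
    source: STSlice,
    graph: SpatialGraph,
    enc_cfg: EncoderConfig,
    cls_cfg: ClassifierConfig,
    train_cfg: TrainConfig,
) -> tuple[EncoderState, ClassifierState, dict[str, list[float]]]:
    """Fit encoder + classifier by full-batch cross-entropy on source labels."""
    if source.labels is None:
        raise ValueError("source slice must carry region labels")
    class_names = sorted(set(map(str, source.labels)))
    if len(class_names) < 2:
        raise ValueError("source labels contain fewer than 2 classes")
    y, y_idx = _one_hot(source.labels, class_names)

    ss = np.random.SeedSequence([train_cfg.seed, 1])
    rng_enc, rng_cls, rng_eps = (np.random.default_rng(s) for s in ss.spawn(3))
    enc_state = EncoderState(enc_cfg, rng_enc)
    cls_state = ClassifierState(cls_cfg, rng_cls)
    opt = Adam(enc_state.parameters() + cls_state.parameters(), lr=train_cfg.lr_source)

    X = Tensor(source.expression)
    g_a, g_p = _propagation(graph, train_cfg.graph_mode)
    history = {"cls_loss": [], "source_acc": []}
    best, wait = np.inf, 0
    for epoch in range(train_cfg.source_epochs):
        eps = sample_eps(rng_eps, source.n_spots, enc_cfg.latent_dim, train_cfg.graph_mode)
        batch = encode(X, g_a, g_p, enc_state, eps, train_cfg.graph_mode)
        probs = classify(batch.h, cls_state, mode="train")
        loss = cross_entropy_loss(probs, y)
        if train_cfg.kl_weight > 0:
            loss = loss + train_cfg.kl_weight * kl_divergence(batch)
        val = float(loss.data)
        if not np.isfinite(val):
            raise RuntimeError(f"non-finite classifier loss at epoch {epoch}")
        acc = float(np.mean(probs.data.argmax(axis=1) == y_idx))
        history["cls_loss"].append(val)
        history["source_acc"].append(acc)
        opt.zero_grad()
        loss.backward()
        opt.step()
        if val < best - train_cfg.plateau_tol:
            best, wait = val, 0
        else:
            wait += 1
            if wait >= train_cfg.plateau_patience:
                break
    return enc_state, cls_state, history


# ---------------------------------------------------------------------------
# phase 2: adversarial adaptation
# ---------------------------------------------------------------------------

def _holdout_split(rng: np.random.Generator, n: int, frac: float):
    perm = rng.permutation(n)
    m = int(np.floor(frac * n))
    return perm[m:], perm[:m]  # train, held-out


def _domain_accuracy(d_s: np.ndarray, d_t: np.ndarray) -> float:
    """Balanced accuracy of the source-vs-target call (threshold 0.5)."""
    m = min(len(d_s), len(d_t))
    return float(0.5 * (np.mean(d_s[:m] > 0.5) + np.mean(d_t[:m] <= 0.5)))


def adapt_target(
    target: STSlice,
    target_graph: SpatialGraph,
    source: STSlice,
    source_graph: SpatialGraph,
    enc_state: EncoderState,
    disc_cfg: DiscriminatorConfig,
    train_cfg: TrainConfig,
) -> tuple[EncoderState, DiscriminatorState, dict[str, list[float]]]:
    """ADDA alternation: discriminator vs target encoder, source frozen.

    Returns the adapted target encoder, the discriminator, and a history
    of per-iteration discriminator loss, generator loss, and balanced
    domain-classification accuracy on held-out embeddings (computed with
    eps = 0).  The source encoder and classifier are never touched.
    """
    mode = train_cfg.graph_mode
    tgt_enc = enc_state.copy()
    ss = np.random.SeedSequence([train_cfg.seed, 2])
    rng_disc, rng_eps, rng_split = (np.random.default_rng(s) for s in ss.spawn(3))
    disc = DiscriminatorState(disc_cfg, rng_disc)
    opt_d = Adam(disc.parameters(), lr=train_cfg.lr_disc)
    opt_g = Adam(tgt_enc.parameters(), lr=train_cfg.lr_target)

    Xs, Xt = Tensor(source.expression), Tensor(target.expression)
    gs_a, gs_p = _propagation(source_graph, mode)
    gt_a, gt_p = _propagation(target_graph, mode)
    lat = enc_state.cfg.latent_dim
    tr_s, ho_s = _holdout_split(rng_split, source.n_spots, train_cfg.holdout_frac)
    tr_t, ho_t = _holdout_split(rng_split, target.n_spots, train_cfg.holdout_frac)

    history = {"d_loss": [], "g_loss": [], "domain_acc": []}
    g_initial, streak = None, 0
    for it in range(train_cfg.adapt_iters):
        for _ in range(train_cfg.d_steps):
            eps_s = sample_eps(rng_eps, source.n_spots, lat, mode)
            eps_t = sample_eps(rng_eps, target.n_spots, lat, mode)
            h_s = encode(Xs, gs_a, gs_p, enc_state, eps_s, mode).h.detach()
            h_t = encode(Xt, gt_a, gt_p, tgt_enc, eps_t, mode).h.detach()
            d_s = discriminate(gather_rows(h_s, tr_s), disc)
            d_t = discriminate(gather_rows(h_t, tr_t), disc)
            loss_d = discriminator_loss(d_s, d_t)
            opt_d.zero_grad()
            loss_d.backward()
            opt_d.step()
        for _ in range(train_cfg.g_steps):
            eps_t = sample_eps(rng_eps, target.n_spots, lat, mode)
            h_t = encode(Xt, gt_a, gt_p, tgt_enc, eps_t, mode).h
            d_t = discriminate(gather_rows(h_t, tr_t), disc)
            loss_g = generator_loss(d_t)
            opt_g.zero_grad()
            opt_d.zero_grad()  # discriminator is frozen in this step
            loss_g.backward()
            opt_g.step()

        val_d, val_g = float(loss_d.data), float(loss_g.data)
        if not (np.isfinite(val_d) and np.isfinite(val_g)):
            raise RuntimeError(f"non-finite adversarial loss at iteration {it}")
        if g_initial is None:
            # floor at the ln 2 equilibrium: a tiny initial L_G (confidently
            # fooled discriminator at init) rising toward ln 2 is not divergence
            g_initial = max(val_g, np.log(2.0))
        if val_g > train_cfg.divergence_factor * g_initial:
            raise RuntimeError(
                f"generator loss diverged at iteration {it}: "
                f"{val_g:.3f} > {train_cfg.divergence_factor} x {g_initial:.3f}"
            )
        # held-out balanced domain accuracy with the deterministic (eps=0) pass
        h_s0 = encode(Xs, gs_a, gs_p, enc_state, None, mode).h.data
        h_t0 = encode(Xt, gt_a, gt_p, tgt_enc, None, mode).h.data
        d_s0 = discriminate(Tensor(h_s0[ho_s]), disc).data.ravel()
        d_t0 = discriminate(Tensor(h_t0[ho_t]), disc).data.ravel()
        acc = _domain_accuracy(d_s0, d_t0)
        history["d_loss"].append(val_d)
        history["g_loss"].append(val_g)
        history["domain_acc"].append(acc)
        # the band rule engages only after a warmup: early on the untrained
        # discriminator sits at chance, which is not convergence
        lo, hi = train_cfg.domain_band
        streak = streak + 1 if lo <= acc <= hi else 0
        if it >= train_cfg.band_warmup and streak >= train_cfg.band_patience:
            break
    return tgt_enc, disc, history


# ---------------------------------------------------------------------------
# prediction and end-to-end driver
# ---------------------------------------------------------------------------

def predict(
    slice_: STSlice,
    graph: SpatialGraph,
    enc_state: EncoderState,
    cls_state: ClassifierState,
    class_names: list[str],
    graph_mode: str = "both",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic (eps = 0) forward pass -> (labels, probabilities, h)."""
    if slice_.n_genes != enc_state.cfg.input_dim:
        raise ValueError(
            f"slice has {slice_.n_genes} genes but the encoder was trained on "
            f"{enc_state.cfg.input_dim}"
        )
    g_a, g_p = _propagation(graph, graph_mode)
    batch = encode(Tensor(slice_.expression), g_a, g_p, enc_state, None, graph_mode)
    probs = classify(batch.h, cls_state, mode="eval").data
    names = np.array(class_names, dtype=object)
    labels = names[probs.argmax(axis=1)]  # argmax ties fall to the lowest index
    return labels, probs, batch.h.data


def run_transfer(
    source: STSlice,
    target: STSlice,
    pre_cfg: PreprocessConfig | None = None,
    train_cfg: TrainConfig | None = None,
    k: int = 6,
    walk_cfg: WalkConfig | None = None,
    enc_cfg: EncoderConfig | None = None,
    cls_cfg: ClassifierConfig | None = None,
    disc_cfg: DiscriminatorConfig | None = None,
    verbose: bool = False,
) -> TransferResult:
    """End-to-end transfer: align -> preprocess -> graphs -> train -> adapt -> predict.

    Target labels, when present, are used only to score the predictions
    (ARI and clustering accuracy in both semantic and matched modes).
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    train_cfg = train_cfg or TrainConfig()
    walk_cfg = walk_cfg or WalkConfig()
    log = (lambda msg: print(f"[stransfer] {msg}")) if verbose else (lambda msg: None)

    t0 = time.time()
    source, target = align_genes(source, target)
    src_p, pre_state = preprocess_expression(source, pre_cfg, return_state=True)
    tgt_p = preprocess_expression(target, state=pre_state)
    log(f"preprocessed: {src_p.n_spots}+{tgt_p.n_spots} spots, "
        f"{src_p.n_genes} genes ({time.time() - t0:.1f}s)")

    include_ppmi = train_cfg.graph_mode in ("ppmi", "both")
    src_graph = build_spatial_graph(src_p.coords, k, walk_cfg, include_ppmi=include_ppmi)
    tgt_graph = build_spatial_graph(tgt_p.coords, k, walk_cfg, include_ppmi=include_ppmi)
    log(f"graphs built (k={k}, T={walk_cfg.walk_length}) ({time.time() - t0:.1f}s)")

    class_names = sorted(set(map(str, src_p.labels)))
    enc_cfg = enc_cfg or EncoderConfig(input_dim=src_p.n_genes)
    if enc_cfg.input_dim != src_p.n_genes:
        raise ValueError("encoder input_dim does not match the aligned gene space")
    cls_cfg = cls_cfg or ClassifierConfig(
        n_classes=len(class_names),
        width=enc_cfg.h_dim,
        variant=train_cfg.classifier_variant,
    )
    disc_cfg = disc_cfg or DiscriminatorConfig(input_dim=enc_cfg.h_dim)

    enc_state, cls_state, src_history = train_source(
        src_p, src_graph, enc_cfg, cls_cfg, train_cfg
    )
    log(f"source phase: {len(src_history['cls_loss'])} epochs, "
        f"final acc {src_history['source_acc'][-1]:.3f} ({time.time() - t0:.1f}s)")

    history = dict(src_history)
    if train_cfg.adaptation:
        tgt_enc, disc, adapt_history = adapt_target(
            tgt_p, tgt_graph, src_p, src_graph, enc_state, disc_cfg, train_cfg
        )
        history.update(adapt_history)
        log(f"adaptation: {len(adapt_history['d_loss'])} iterations, "
            f"final domain acc {adapt_history['domain_acc'][-1]:.3f} "
            f"({time.time() - t0:.1f}s)")
    else:
        tgt_enc = enc_state

    labels, probs, h_t = predict(
        tgt_p, tgt_graph, tgt_enc, cls_state, class_names, train_cfg.graph_mode
    )
    _, _, h_s = predict(
        src_p, src_graph, enc_state, cls_state, class_names, train_cfg.graph_mode
    )

    metrics = {
        "source_train_accuracy": history["source_acc"][-1],
        "domain_accuracy": history["domain_acc"][-1] if "domain_acc" in history else None,
    }
    if tgt_p.labels is not None:
        metrics["ari"] = evaluation.adjusted_rand_index(tgt_p.labels, labels)
        metrics["ca"] = evaluation.clustering_accuracy(tgt_p.labels, labels, "semantic")
        metrics["ca_matched"] = evaluation.clustering_accuracy(tgt_p.labels, labels, "matched")
        log(f"target metrics: ARI {metrics['ari']:.3f}, CA {metrics['ca']:.3f}")

    config = {
        "preprocess": asdict(pre_cfg),
        "train": asdict(train_cfg),
        "encoder": asdict(enc_cfg),
        "classifier": asdict(cls_cfg),
        "discriminator": asdict(disc_cfg),
        "k": k,
        "walk": asdict(walk_cfg),
        "class_names": class_names,
    }
    return TransferResult(
        predicted_labels=labels,
        probabilities=probs,
        class_names=class_names,
        spot_ids=tgt_p.spot_ids,
        source_embeddings=h_s,
        target_embeddings=h_t,
        history=history,
        metrics=metrics,
        config=config,
    )


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(
    path,
    enc_state: EncoderState,
    cls_state: ClassifierState,
    class_names: list[str],
    pre_state: PreprocessState | None = None,
    disc_state: DiscriminatorState | None = None,
) -> None:
    """Single-file .npz checkpoint: all parameters plus a JSON metadata blob."""
    arrays = {}
    for k, v in enc_state.state_arrays().items():
        arrays[f"enc/{k}"] = v
    for k, v in cls_state.state_arrays().items():
        arrays[f"cls/{k}"] = v
    if disc_state is not None:
        for k, v in disc_state.state_arrays().items():
            arrays[f"disc/{k}"] = v
    meta = {
        "encoder_cfg": asdict(enc_state.cfg),
        "classifier_cfg": asdict(cls_state.cfg),
        "discriminator_cfg": asdict(disc_state.cfg) if disc_state is not None else None,
        "class_names": list(class_names),
    }
    if pre_state is not None:
        meta["preprocess_cfg"] = asdict(pre_state.cfg)
        arrays["pre/gene_means"] = np.asarray(pre_state.gene_means, dtype=float)
        arrays["pre/gene_sds"] = np.asarray(pre_state.gene_sds, dtype=float)
        meta["hvg_genes"] = [str(g) for g in pre_state.hvg_genes]
    arrays["meta_json"] = np.array(json.dumps(meta))
    np.savez(Path(path), **arrays)


def load_checkpoint(path):
    """Inverse of :func:`save_checkpoint`.

    Returns (enc_state, cls_state, class_names, pre_state, disc_state);
    pre_state/disc_state are None when absent from the file.
    """
    with np.load(Path(path), allow_pickle=False) as data:
        arrays = {k: data[k] for k in data.files}
    meta = json.loads(str(arrays.pop("meta_json")))
    enc_cfg = EncoderConfig(**{**meta["encoder_cfg"],
                               "gcn_dims": tuple(meta["encoder_cfg"]["gcn_dims"])})
    rng = np.random.default_rng(0)
    enc_state = EncoderState(enc_cfg, rng)
    enc_state.load_arrays({k[4:]: v for k, v in arrays.items() if k.startswith("enc/")})
    cls_cfg = ClassifierConfig(**meta["classifier_cfg"])
    cls_state = ClassifierState(cls_cfg, rng)
    cls_state.load_arrays({k[4:]: v for k, v in arrays.items() if k.startswith("cls/")})
    disc_state = None
    if meta.get("discriminator_cfg") is not None:
        dc = meta["discriminator_cfg"]
        disc_state = DiscriminatorState(
            DiscriminatorConfig(input_dim=dc["input_dim"], hidden=tuple(dc["hidden"])), rng
        )
        disc_state.load_arrays(
            {k[5:]: v for k, v in arrays.items() if k.startswith("disc/")}
        )
    pre_state = None
    if "hvg_genes" in meta:
        pre_state = PreprocessState(
            hvg_genes=np.array(meta["hvg_genes"], dtype=object),
            gene_means=arrays["pre/gene_means"],
            gene_sds=arrays["pre/gene_sds"],
            cfg=PreprocessConfig(**meta["preprocess_cfg"]),
        )
    return enc_state, cls_state, meta["class_names"], pre_state, disc_state
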