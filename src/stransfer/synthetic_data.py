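"""Synthetic paired-slice generator: the package's self-contained test bed.

Emulates the transfer setting the model is built for: two adjacent tissue
slices drawn from one generative law — spatially contiguous expression
domains (cortical-layer-like strips, or Gaussian blobs) with
domain-specific marker genes — where the source slice keeps its region
labels and the target slice carries an additional gene-wise multiplicative
batch effect, the platform/library-style shift that adversarial adaptation
is meant to neutralize.  Target labels are generated too but exist purely
for evaluation.

Expression follows a log-normal count model: baseline per-gene log-means
are standard normal, a domain's marker genes gain ``+effect_size`` on the
log scale for member spots, spot-level noise is Gaussian on the log scale,
and values are exponentiated and rounded to counts.  The log-normal choice
keeps every moment used in tests available in closed form; a negative
binomial switch is provided for realism checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_preprocess import STSlice


@dataclass
class SyntheticConfig:
    """Generative settings; defaults define the package's study conditions."""

    n_spots: int = 400
    n_genes: int = 60
    n_domains: int = 4
    layout: str = "strips"  # or "blobs"
    markers_per_domain: int = 8
    effect_size: float = 2.0  # log-scale mean shift on marker genes
    noise_sd: float = 0.6  # log-scale spot noise
    batch_shift: float = 1.0  # sd of gene-wise log-normal batch factors
    batch_frac: float = 0.5  # fraction of genes the batch effect touches
    coordinate_jitter: float = 0.1  # grid-unit sd of positional jitter
    count_model: str = "lognormal"  # or "nb"
    nb_dispersion: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_domains < 2:
            raise ValueError("need at least 2 domains")
        if self.n_spots < self.n_domains:
            raise ValueError("need at least one spot per domain")
        if min(self.effect_size, self.noise_sd, self.batch_shift) < 0:
            raise ValueError("effect_size, noise_sd and batch_shift must be >= 0")
        if not 0.0 <= self.batch_frac <= 1.0:
            raise ValueError("batch_frac must be in [0, 1]")
        if self.layout not in ("strips", "blobs"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.markers_per_domain * self.n_domains > self.n_genes:
            raise ValueError("marker sets exceed the gene panel")

    def domain_names(self) -> list[str]:
        return [f"D{i + 1}" for i in range(self.n_domains)]


@dataclass
class DomainModel:
    """Gene-level parameters shared by both slices of a pair."""

    baseline_logmean: np.ndarray  # (G,)
    marker_sets: list[np.ndarray]  # per-domain gene indices


def make_domain_model(cfg: SyntheticConfig, rng: np.random.Generator) -> DomainModel:
    baseline = rng.standard_normal(cfg.n_genes)
    m = cfg.markers_per_domain
    markers = [np.arange(c * m, (c + 1) * m) for c in range(cfg.n_domains)]
    return DomainModel(baseline_logmean=baseline, marker_sets=markers)


def generate_layout(
    cfg: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Spot coordinates and integer domain labels (0..C-1), all domains non-empty.

    Strips: a jittered square grid banded into C contiguous layers by
    y-coordinate quantiles.  Blobs: equal-sized clouds around Gaussian
    centers placed on a circle.
    """
    n, c = cfg.n_spots, cfg.n_domains
    if cfg.layout == "strips":
        side = int(np.ceil(np.sqrt(n)))
        gx, gy = np.meshgrid(np.arange(side), np.arange(side))
        coords = np.column_stack([gx.ravel()[:n], gy.ravel()[:n]]).astype(float)
        coords += rng.normal(0.0, cfg.coordinate_jitter, size=coords.shape)
        edges = np.quantile(coords[:, 1], np.linspace(0, 1, c + 1)[1:-1])
        labels = np.searchsorted(edges, coords[:, 1], side="right")
    else:
        angles = 2 * np.pi * np.arange(c) / c
        centers = np.column_stack([np.cos(angles), np.sin(angles)]) * 3.0
        labels = np.repeat(np.arange(c), int(np.ceil(n / c)))[:n]
        coords = centers[labels] + rng.normal(0.0, 0.6, size=(n, 2))
        coords += rng.normal(0.0, cfg.coordinate_jitter, size=coords.shape)
    # quantile banding can starve an extreme band only in degenerate configs
    for d in range(c):
        if not np.any(labels == d):
            labels[np.argsort(coords[:, 1])[d]] = d
    return coords, labels


def generate_expression(
    labels: np.ndarray,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    model: DomainModel | None = None,
) -> np.ndarray:
    """Counts from the log-normal (or NB) domain-marker model."""
    model = model or make_domain_model(cfg, rng)
    n = len(labels)
    logmean = np.tile(model.baseline_logmean, (n, 1))
    for d, genes in enumerate(model.marker_sets):
        member = labels == d
        logmean[np.ix_(member, genes)] += cfg.effect_size
    if cfg.count_model == "lognormal":
        logx = logmean + rng.normal(0.0, cfg.noise_sd, size=logmean.shape)
        return np.round(np.exp(logx))
    if cfg.count_model == "nb":
        mean = np.exp(logmean + rng.normal(0.0, cfg.noise_sd, size=logmean.shape))
        r = cfg.nb_dispersion
        return rng.negative_binomial(r, r / (r + mean)).astype(float)
    raise ValueError(f"unknown count_model {cfg.count_model!r}")


def apply_batch_effect(
    X: np.ndarray, cfg: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Scale a random gene subset by shared log-normal factors.

    One factor per affected gene, identical across spots — a library- or
    platform-style technical shift.  Zero shift or zero fraction is the
    identity.
    """
    if np.any(X < 0):
        raise ValueError("expression must be non-negative")
    g = X.shape[1]
    n_affected = int(np.floor(cfg.batch_frac * g))
    if cfg.batch_shift == 0 or n_affected == 0:
        return X.copy()
    genes = rng.choice(g, size=n_affected, replace=False)
    factors = np.exp(rng.normal(0.0, cfg.batch_shift, size=n_affected))
    out = X.copy()
    out[:, genes] *= factors
    return out


def generate_slice_pair(cfg: SyntheticConfig | None = None) -> tuple[STSlice, STSlice]:
    """Labeled source slice and batch-shifted target slice from one law.

    Domain-level parameters (baseline log-means, marker assignments) are
    drawn once and shared; spot layouts and noise are independent draws.
    The target keeps its labels solely so predictions can be scored.
    """
    cfg = cfg or SyntheticConfig()
    ss = np.random.SeedSequence(cfg.seed)
    rng_model, rng_src, rng_tgt, rng_batch = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    model = make_domain_model(cfg, rng_model)
    names = np.array(cfg.domain_names(), dtype=object)
    genes = np.array([f"g{j}" for j in range(cfg.n_genes)], dtype=object)

    slices = []
    for role, rng in (("source", rng_src), ("target", rng_tgt)):
        coords, labels = generate_layout(cfg, rng)
        X = generate_expression(labels, cfg, rng, model)
        if role == "target":
            X = apply_batch_effect(X, cfg, rng_batch)
        slices.append(
            STSlice(
                expression=X,
                coords=coords,
                spot_ids=np.array([f"{role}_{i}" for i in range(len(labels))], dtype=object),
                gene_ids=genes,
                labels=names[labels],
                slice_id=role,
            )
        )
    return slices[0], slices[1]
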