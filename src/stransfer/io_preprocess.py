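"""Slice I/O, gene-space alignment and expression preprocessing.

A tissue slice is a pair ``(X, S)``: an ``N x G`` spot-by-gene expression
matrix and an ``N x 2`` matrix of planar spot coordinates, optionally with
per-spot region labels on an annotated slice.  Slices are read/written as
h5ad (via :mod:`anndata`) or as a CSV pair (expression table + coordinate
table keyed by spot id).

Preprocessing follows the standard recipe for spot-level data: total-count
normalization, log1p, dispersion-ranked highly-variable-gene selection and
per-gene z-scoring.  HVG selection and scaling statistics are fit on the
labeled source slice and applied unchanged to the target slice, so both
slices enter the model in the identical feature space and any systematic
target-vs-source shift is preserved for the adaptation module to remove
rather than silently cancelled during preprocessing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Input file lacks a required slot/column."""


class AlignmentError(ValueError):
    """Spot or gene identifiers do not line up across tables/slices."""


@dataclass
class STSlice:
    """One tissue slice: expression, coordinates, and optional region labels."""

    expression: np.ndarray
    coords: np.ndarray
    spot_ids: np.ndarray
    gene_ids: np.ndarray
    labels: np.ndarray | None = None
    slice_id: str = "slice"

    def __post_init__(self):
        self.expression = np.asarray(self.expression, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
        self.validate()

    def validate(self) -> None:
        n, g = self.expression.shape
        if self.coords.shape != (n, 2):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match {n} spots x 2"
            )
        if len(self.spot_ids) != n:
            raise ValueError("spot_ids length mismatch")
        if len(self.gene_ids) != g:
            raise ValueError("gene_ids length mismatch")
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels length mismatch")
        if len(set(self.spot_ids)) != n:
            raise ValueError("spot_ids not unique")
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene_ids not unique")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        if not np.all(np.isfinite(self.expression)):
            raise ValueError("expression contains non-finite values")

    @property
    def n_spots(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    @property
    def n_classes(self) -> int:
        if self.labels is None:
            raise ValueError("slice has no labels")
        return len(set(self.labels))

    def subset_spots(self, idx) -> "STSlice":
        return STSlice(
            expression=self.expression[idx],
            coords=self.coords[idx],
            spot_ids=self.spot_ids[idx],
            gene_ids=self.gene_ids,
            labels=None if self.labels is None else self.labels[idx],
            slice_id=self.slice_id,
        )

    def subset_genes(self, idx) -> "STSlice":
        return STSlice(
            expression=self.expression[:, idx],
            coords=self.coords,
            spot_ids=self.spot_ids,
            gene_ids=self.gene_ids[idx],
            labels=self.labels,
            slice_id=self.slice_id,
        )

    def to_anndata(self, spatial_key: str = "spatial", label_key: str = "region") -> ad.AnnData:
        obs = pd.DataFrame(index=pd.Index(self.spot_ids.astype(str), name="spot_id"))
        if self.labels is not None:
            obs[label_key] = pd.Categorical(self.labels.astype(str))
        adata = ad.AnnData(
            X=self.expression.copy(),
            obs=obs,
            var=pd.DataFrame(index=pd.Index(self.gene_ids.astype(str), name="gene_id")),
        )
        adata.obsm[spatial_key] = self.coords.copy()
        adata.uns["slice_id"] = self.slice_id
        return adata


@dataclass
class PreprocessConfig:
    """Expression preprocessing switches (field-standard defaults)."""

    target_sum: float = 1e4
    log1p: bool = True
    n_hvg: int = 3000  # 0 keeps all genes
    scale: bool = True
    clip: float | None = 10.0

    def __post_init__(self):
        if self.target_sum <= 0:
            raise ValueError("target_sum must be positive")
        if self.n_hvg < 0:
            raise ValueError("n_hvg must be >= 0")


@dataclass
class PreprocessState:
    """Source-fitted choices reapplied to the target slice."""

    hvg_genes: np.ndarray | None = None  # gene ids retained, in order
    gene_means: np.ndarray | None = None
    gene_sds: np.ndarray | None = None
    cfg: PreprocessConfig = field(default_factory=PreprocessConfig)


# ---------------------------------------------------------------------------
# reading and writing
# ---------------------------------------------------------------------------

def read_slice(
    path,
    format: str = "h5ad",
    spatial_key: str = "spatial",
    label_key: str = "region",
    slice_id: str | None = None,
) -> STSlice:
    """Read one slice from an h5ad file or a CSV-pair directory.

    For ``csv_pair``, `path` is a directory holding ``expression.csv``
    (spot_id + one column per gene) and ``coords.csv`` (spot_id, x, y and
    optionally a label column named `label_key`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "h5ad":
        adata = ad.read_h5ad(path)
        if spatial_key in adata.obsm:
            coords = np.asarray(adata.obsm[spatial_key], dtype=float)[:, :2]
        elif {"x", "y"}.issubset(adata.obs.columns):
            coords = adata.obs[["x", "y"]].to_numpy(dtype=float)
        else:
            raise FormatError(
                f"no coordinates: expected obsm[{spatial_key!r}] or obs columns 'x','y'"
            )
        X = adata.X
        X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
        labels = (
            adata.obs[label_key].astype(str).to_numpy()
            if label_key in adata.obs.columns
            else None
        )
        return STSlice(
            expression=X,
            coords=coords,
            spot_ids=adata.obs_names.to_numpy(),
            gene_ids=adata.var_names.to_numpy(),
            labels=labels,
            slice_id=slice_id or str(adata.uns.get("slice_id", path.stem)),
        )
    if format == "csv_pair":
        expr = pd.read_csv(path / "expression.csv", index_col=0)
        coords = pd.read_csv(path / "coords.csv", index_col=0)
        missing = expr.index.difference(coords.index)
        extra = coords.index.difference(expr.index)
        if len(missing) or len(extra):
            raise AlignmentError(
                "spot ids differ between expression and coordinate tables: "
                f"missing from coords {list(missing[:10])}, "
                f"missing from expression {list(extra[:10])}"
            )
        coords = coords.loc[expr.index]
        labels = coords[label_key].astype(str).to_numpy() if label_key in coords.columns else None
        return STSlice(
            expression=expr.to_numpy(dtype=float),
            coords=coords[["x", "y"]].to_numpy(dtype=float),
            spot_ids=expr.index.to_numpy(dtype=object),
            gene_ids=expr.columns.to_numpy(dtype=object),
            labels=labels,
            slice_id=slice_id or path.name,
        )
    raise ValueError(f"unknown format {format!r}")


def write_slice(
    slice_: STSlice,
    path,
    format: str = "h5ad",
    spatial_key: str = "spatial",
    label_key: str = "region",
) -> None:
    path = Path(path)
    if format == "h5ad":
        path.parent.mkdir(parents=True, exist_ok=True)
        slice_.to_anndata(spatial_key, label_key).write_h5ad(path)
    elif format == "csv_pair":
        path.mkdir(parents=True, exist_ok=True)
        expr = pd.DataFrame(
            slice_.expression,
            index=pd.Index(slice_.spot_ids.astype(str), name="spot_id"),
            columns=slice_.gene_ids.astype(str),
        )
        expr.to_csv(path / "expression.csv")
        coords = pd.DataFrame(
            slice_.coords,
            index=expr.index,
            columns=["x", "y"],
        )
        if slice_.labels is not None:
            coords[label_key] = slice_.labels.astype(str)
        coords.to_csv(path / "coords.csv")
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# gene alignment and preprocessing
# ---------------------------------------------------------------------------

def align_genes(source: STSlice, target: STSlice) -> tuple[STSlice, STSlice]:
    """Restrict both slices to their shared genes, in source gene order."""
    target_set = set(target.gene_ids)
    shared = [g for g in source.gene_ids if g in target_set]
    if not shared:
        raise AlignmentError("source and target share no genes")
    src_pos = {g: i for i, g in enumerate(source.gene_ids)}
    tgt_pos = {g: i for i, g in enumerate(target.gene_ids)}
    s_idx = np.array([src_pos[g] for g in shared])
    t_idx = np.array([tgt_pos[g] for g in shared])
    return source.subset_genes(s_idx), target.subset_genes(t_idx)


def _dispersion(X: np.ndarray) -> np.ndarray:
    """Per-gene dispersion (variance / mean) with 0 where the mean is 0."""
    mean = X.mean(axis=0)
    var = X.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    return disp


def preprocess_expression(
    slice_: STSlice,
    cfg: PreprocessConfig | None = None,
    state: PreprocessState | None = None,
    return_state: bool = False,
):
    """Normalize, log-transform, select HVGs and z-score one slice.

    With ``state=None`` the HVG set and scaling statistics are fit on this
    slice (and returned when `return_state`); passing a fitted state applies
    the source's gene set and scaler to a target slice unchanged.
    """
    cfg = cfg if cfg is not None else (state.cfg if state is not None else PreprocessConfig())
    if np.any(slice_.expression < 0):
        raise ValueError("expression must be non-negative before preprocessing")

    X = slice_.expression.copy()
    totals = X.sum(axis=1)
    keep = totals > 0
    if not np.all(keep):
        warnings.warn(
            f"dropping {int((~keep).sum())} all-zero spot(s) from slice "
            f"{slice_.slice_id!r}", stacklevel=2,
        )
        slice_ = slice_.subset_spots(keep)
        X = X[keep]
        totals = totals[keep]

    X = X * (cfg.target_sum / totals)[:, None]
    if cfg.log1p:
        X = np.log1p(X)

    gene_ids = slice_.gene_ids
    fitting = state is None
    state = state if state is not None else PreprocessState(cfg=cfg)

    if fitting:
        if cfg.n_hvg > 0 and cfg.n_hvg < X.shape[1]:
            disp = _dispersion(X)
            # descending dispersion, ties to the lower gene index
            order = np.lexsort((np.arange(len(disp)), -disp))[: cfg.n_hvg]
            order = np.sort(order)  # keep original gene order
            state.hvg_genes = gene_ids[order]
        else:
            state.hvg_genes = gene_ids.copy()

    pos = {g: i for i, g in enumerate(gene_ids)}
    try:
        col = np.array([pos[g] for g in state.hvg_genes])
    except KeyError as e:
        raise AlignmentError(f"gene {e.args[0]!r} from the fitted state is absent") from e
    X = X[:, col]
    gene_ids = gene_ids[col]

    if cfg.scale:
        if fitting:
            state.gene_means = X.mean(axis=0)
            sds = X.std(axis=0)
            state.gene_sds = np.where(sds > 0, sds, 1.0)
        X = (X - state.gene_means) / state.gene_sds
        if cfg.clip is not None:
            X = np.clip(X, -cfg.clip, cfg.clip)

    out = STSlice(
        expression=X,
        coords=slice_.coords,
        spot_ids=slice_.spot_ids,
        gene_ids=gene_ids,
        labels=slice_.labels,
        slice_id=slice_.slice_id,
    )
    return (out, state) if return_state else out


# ---------------------------------------------------------------------------
# result output
# ---------------------------------------------------------------------------

def write_result(result, out_dir) -> dict[str, Path]:
    """Write predictions, fused embeddings and the metrics/config JSON.

    `result` is a :class:`stransfer.training.TransferResult`.  Returns the
    paths written, keyed by artifact name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    pred = pd.DataFrame(
        {
            "spot_id": result.spot_ids.astype(str),
            "predicted_label": result.predicted_labels.astype(str),
        }
    )
    for j, name in enumerate(result.class_names):
        pred[f"prob_{name}"] = result.probabilities[:, j]
    pred_path = out_dir / "predictions.csv"
    pred.to_csv(pred_path, index=False)

    emb = pd.DataFrame(
        result.target_embeddings,
        index=pd.Index(result.spot_ids.astype(str), name="spot_id"),
        columns=[f"h{j}" for j in range(result.target_embeddings.shape[1])],
    )
    emb_path = out_dir / "embeddings.csv"
    emb.to_csv(emb_path)

    meta = {
        "metrics": result.metrics,
        "config": result.config,
        "history": {k: list(map(float, v)) for k, v in result.history.items()},
    }
    meta_path = out_dir / "metrics.json"
    meta_path.write_text(json.dumps(meta, indent=2, default=float))
    return {"predictions": pred_path, "embeddings": emb_path, "metrics": meta_path}
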