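"""Training orchestration: determinism, phase isolation, prediction, CLI.

These tests run the full pipeline at reduced scale (tens of spots, tens
of epochs) — enough to exercise every code path; the convergence-quality
checks at the study scale live in the acceptance suite.
"""

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from stransfer.cli import main as cli_main
from stransfer.encoder import EncoderConfig
from stransfer.graphs import WalkConfig, build_spatial_graph
from stransfer.heads import ClassifierConfig, DiscriminatorConfig
from stransfer.io_preprocess import PreprocessConfig, preprocess_expression, write_slice
from stransfer.synthetic_data import SyntheticConfig, generate_slice_pair
from stransfer.training import (
    TrainConfig,
    adapt_target,
    load_checkpoint,
    predict,
    run_transfer,
    save_checkpoint,
    train_source,
)

SMALL_GEN = dict(n_spots=80, n_genes=24, n_domains=3, markers_per_domain=5)


def small_pair(seed=0, **kw):
    return generate_slice_pair(SyntheticConfig(seed=seed, **{**SMALL_GEN, **kw}))


def small_train_cfg(**kw):
    defaults = dict(seed=0, source_epochs=150, adapt_iters=30, band_warmup=30)
    defaults.update(kw)
    return TrainConfig(**defaults)


@pytest.fixture(scope="module")
def trained_small():
    """One small source phase shared by several read-only tests."""
    src, tgt = small_pair()
    src_p, pre_state = preprocess_expression(src, PreprocessConfig(n_hvg=0), return_state=True)
    graph = build_spatial_graph(src_p.coords, k=4, walk_cfg=WalkConfig(walk_length=2))
    enc_cfg = EncoderConfig(input_dim=src_p.n_genes, embed_dim=32, gcn_dims=(16, 8, 8))
    cls_cfg = ClassifierConfig(n_classes=3, width=enc_cfg.h_dim)
    enc, cls, hist = train_source(src_p, graph, enc_cfg, cls_cfg, small_train_cfg())
    return src_p, pre_state, graph, enc_cfg, cls_cfg, enc, cls, hist


def test_source_training_loss_decreases_and_accuracy_rises(trained_small):
    *_, hist = trained_small
    loss = np.array(hist["cls_loss"])
    assert loss[-1] < loss[0]
    # 20-epoch moving average is non-increasing (small tolerance for noise)
    ma = np.convolve(loss, np.ones(20) / 20, mode="valid")
    assert np.all(np.diff(ma) <= 1e-3)
    assert hist["source_acc"][-1] > 0.9


def test_predict_reproduces_train_accuracy_on_source(trained_small):
    src_p, _, graph, _, _, enc, cls, hist = trained_small
    labels, probs, h = predict(src_p, graph, enc, cls, sorted(set(src_p.labels)))
    acc = np.mean(labels == src_p.labels)
    # train-time accuracy is computed under sampled eps, prediction under
    # eps=0; at this small scale the sampling noise leaves a few-spot gap
    assert abs(acc - hist["source_acc"][-1]) <= 0.05
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)


def test_predict_is_bit_identical_across_calls(trained_small):
    src_p, _, graph, _, _, enc, cls, _ = trained_small
    names = sorted(set(src_p.labels))
    _, p1, h1 = predict(src_p, graph, enc, cls, names)
    _, p2, h2 = predict(src_p, graph, enc, cls, names)
    assert np.array_equal(p1, p2) and np.array_equal(h1, h2)


def test_predict_rejects_gene_space_mismatch(trained_small):
    src_p, _, graph, _, _, enc, cls, _ = trained_small
    bad = src_p.subset_genes(np.arange(src_p.n_genes - 1))
    with pytest.raises(ValueError, match="genes"):
        predict(bad, graph, enc, cls, sorted(set(src_p.labels)))


def test_single_class_source_rejected(trained_small):
    src_p, _, graph, enc_cfg, cls_cfg, *_ = trained_small
    mono = src_p.subset_spots(np.arange(src_p.n_spots))
    mono.labels = np.array(["only"] * mono.n_spots, dtype=object)
    with pytest.raises(ValueError, match="class"):
        train_source(mono, graph, enc_cfg, cls_cfg, small_train_cfg())


def test_checkpoint_round_trip(tmp_path, trained_small):
    src_p, pre_state, graph, _, _, enc, cls, _ = trained_small
    names = sorted(set(src_p.labels))
    path = tmp_path / "model.npz"
    save_checkpoint(path, enc, cls, names, pre_state=pre_state)
    enc2, cls2, names2, pre2, disc2 = load_checkpoint(path)
    assert names2 == names and disc2 is None
    np.testing.assert_array_equal(pre2.hvg_genes, pre_state.hvg_genes)
    _, p1, _ = predict(src_p, graph, enc, cls, names)
    _, p2, _ = predict(src_p, graph, enc2, cls2, names2)
    assert np.array_equal(p1, p2)


def test_adaptation_freezes_classifier_and_source_encoder(trained_small):
    """Phase isolation: adapt_target must not touch phase-1 parameters."""
    src_p, pre_state, graph, enc_cfg, cls_cfg, enc, cls, _ = trained_small
    _, tgt = small_pair()
    tgt_p = preprocess_expression(tgt, state=pre_state)
    tgt_graph = build_spatial_graph(tgt_p.coords, k=4, walk_cfg=WalkConfig(walk_length=2))
    enc_before = {k: v.copy() for k, v in enc.state_arrays().items()}
    cls_before = {k: v.copy() for k, v in cls.state_arrays().items()}
    tgt_enc, disc, hist = adapt_target(
        tgt_p, tgt_graph, src_p, graph, enc,
        DiscriminatorConfig(input_dim=enc_cfg.h_dim), small_train_cfg(),
    )
    for k, v in enc.state_arrays().items():
        assert np.array_equal(v, enc_before[k]), k
    for k, v in cls.state_arrays().items():
        assert np.array_equal(v, cls_before[k]), k
    # and the target encoder did actually move
    assert any(
        not np.array_equal(tgt_enc.state_arrays()[k], enc_before[k]) for k in enc_before
    )
    assert len(hist["d_loss"]) == len(hist["g_loss"]) == len(hist["domain_acc"])


def test_end_to_end_same_seed_bit_identical():
    src, tgt = small_pair()
    cfg = small_train_cfg(adapt_iters=15)
    r1 = run_transfer(src, tgt, pre_cfg=PreprocessConfig(n_hvg=0), train_cfg=cfg, k=4)
    r2 = run_transfer(src, tgt, pre_cfg=PreprocessConfig(n_hvg=0), train_cfg=cfg, k=4)
    assert np.array_equal(r1.probabilities, r2.probabilities)
    assert np.array_equal(r1.predicted_labels, r2.predicted_labels)
    assert r1.history == r2.history
    assert np.array_equal(r1.target_embeddings, r2.target_embeddings)


@pytest.mark.parametrize("mode", ["knn", "ppmi"])
def test_single_graph_modes_run_end_to_end(mode):
    src, tgt = small_pair()
    cfg = small_train_cfg(graph_mode=mode, adapt_iters=10)
    res = run_transfer(src, tgt, pre_cfg=PreprocessConfig(n_hvg=0), train_cfg=cfg, k=4)
    assert set(res.predicted_labels) <= set(res.class_names)
    assert res.metrics["ari"] is not None


def test_adaptation_harmless_without_batch_shift():
    """Source and target drawn from one law: adaptation must not hurt."""
    src, tgt = generate_slice_pair(
        SyntheticConfig(seed=0, n_spots=200, batch_shift=0.0)
    )
    common = dict(pre_cfg=PreprocessConfig(n_hvg=0), k=6)
    on = run_transfer(src, tgt, train_cfg=TrainConfig(seed=0, source_epochs=120,
                                                      adapt_iters=150), **common)
    off = run_transfer(src, tgt, train_cfg=TrainConfig(seed=0, source_epochs=120,
                                                       adaptation=False), **common)
    assert abs(on.metrics["ca"] - off.metrics["ca"]) <= 0.05


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def test_cli_simulate_run_eval_round_trip(tmp_path):
    runner = CliRunner()
    data = tmp_path / "data"
    sim = runner.invoke(cli_main, [
        "simulate", "--out", str(data), "--format", "csv_pair",
        "--n-spots", "80", "--n-genes", "24", "--n-domains", "3", "--seed", "0",
    ])
    assert sim.exit_code == 0, sim.output

    out = tmp_path / "run"
    cfg_file = tmp_path / "cfg.yaml"
    cfg_file.write_text(yaml.safe_dump({"source_epochs": 40, "adapt_iters": 10,
                                        "n_hvg": 0, "k": 4}))
    run = runner.invoke(cli_main, [
        "run", "--source", str(data / "source"), "--target", str(data / "target"),
        "--out", str(out), "--config", str(cfg_file), "--seed", "0", "--quiet",
    ])
    assert run.exit_code == 0, run.output
    assert (out / "predictions.csv").exists()
    assert (out / "embeddings.csv").exists()
    assert (out / "metrics.json").exists()

    ev = runner.invoke(cli_main, [
        "eval", "--truth", str(data / "target" / "coords.csv"),
        "--pred", str(out / "predictions.csv"),
        "--out", str(tmp_path / "report.json"),
    ])
    assert ev.exit_code == 0, ev.output
    assert "ARI" in ev.output


def test_cli_staged_train_adapt_predict(tmp_path):
    runner = CliRunner()
    data = tmp_path / "data"
    sim = runner.invoke(cli_main, [
        "simulate", "--out", str(data), "--format", "csv_pair",
        "--n-spots", "60", "--n-genes", "20", "--n-domains", "3",
        "--markers-per-domain", "4", "--seed", "1",
    ])
    assert sim.exit_code == 0, sim.output
    common = ["--k", "4", "--walk-len", "2"]
    tr = runner.invoke(cli_main, [
        "train", "--source", str(data / "source"),
        "--checkpoint", str(tmp_path / "src.npz"),
        "--n-hvg", "0", "--source-epochs", "30", *common,
    ])
    assert tr.exit_code == 0, tr.output
    ad = runner.invoke(cli_main, [
        "adapt", "--source", str(data / "source"), "--target", str(data / "target"),
        "--checkpoint", str(tmp_path / "src.npz"),
        "--out-checkpoint", str(tmp_path / "tgt.npz"),
        "--adapt-iters", "10", *common,
    ])
    assert ad.exit_code == 0, ad.output
    pr = runner.invoke(cli_main, [
        "predict", "--slice", str(data / "target"),
        "--checkpoint", str(tmp_path / "tgt.npz"),
        "--out", str(tmp_path / "pred.csv"), *common,
    ])
    assert pr.exit_code == 0, pr.output
    import pandas as pd

    df = pd.read_csv(tmp_path / "pred.csv")
    assert len(df) == 60
    prob_cols = [c for c in df.columns if c.startswith("prob_")]
    np.testing.assert_allclose(df[prob_cols].sum(axis=1), 1.0, atol=1e-6)


def test_cli_graph_export(tmp_path):
    runner = CliRunner()
    data = tmp_path / "data"
    sim = runner.invoke(cli_main, [
        "simulate", "--out", str(data), "--format", "csv_pair",
        "--n-spots", "40", "--n-genes", "15", "--n-domains", "2",
        "--markers-per-domain", "4", "--seed", "2",
    ])
    assert sim.exit_code == 0, sim.output
    g = runner.invoke(cli_main, [
        "graph", "--slice", str(data / "source"), "--out", str(tmp_path / "g"),
        "--k", "4", "--walk-len", "2",
    ])
    assert g.exit_code == 0, g.output
    from scipy.io import mmread

    a = mmread(tmp_path / "g" / "knn_adjacency.mtx").toarray()
    assert a.shape == (40, 40) and np.array_equal(a, a.T)
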