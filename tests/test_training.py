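"""Training harness: determinism, overfit smoke checks, evaluation
equivalence with direct metric calls, ablation bookkeeping, and the CLI."""

import json

import numpy as np
import pytest

from msunet import nn
from msunet.architectures import network_from_name
from msunet.metrics import confusion_counts, iou
from msunet.synthetic import Dataset, SyntheticStyle, make_splits, synthesize_dataset
from msunet.training import (TrainConfig, compare, config_from_yaml, evaluate,
                             run_ablation, train, all31_names)

TINY = dict(levels=3, base_width=4)


def _tiny_net(seed=0):
    return network_from_name("unet", seed=seed, **TINY)


class TestTrainConfig:
    def test_defaults_follow_protocol(self):
        cfg = TrainConfig()
        assert cfg.learning_rate == 1e-2 and cfg.momentum == 0.9
        assert cfg.loss == "bce"

    def test_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0)
        with pytest.raises(ValueError):
            TrainConfig(loss="hinge")
        with pytest.raises(ValueError):
            TrainConfig(epochs=-1)

    def test_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("epochs: 3\nloss: dice\nseed: 9\n")
        cfg = config_from_yaml(p)
        assert (cfg.epochs, cfg.loss, cfg.seed) == (3, "dice", 9)
        p.write_text("optimizer: adam\n")
        with pytest.raises(ValueError, match="unknown config keys"):
            config_from_yaml(p)


class TestTrain:
    def test_zero_epochs_keeps_initial_weights(self, blob_dataset):
        ds, splits = blob_dataset
        net = _tiny_net()
        before = {k: v.copy() for k, v in net.state_dict().items()}
        res = train(net, splits, ds, TrainConfig(epochs=0), folds=[0])
        for k, v in res.network.state_dict().items():
            np.testing.assert_array_equal(v, before[k])

    def test_overfit_single_batch_loss_decreases(self):
        """50 steps on one repeated batch: loss strictly decreases over the
        window, allowing plateaus shorter than 5 steps."""
        ds = synthesize_dataset(SyntheticStyle("blobs"), 4, seed=5)
        net = _tiny_net(seed=2)
        opt = nn.SGD(net.parameters(), lr=1e-2, momentum=0.9)
        x = nn.Tensor(np.stack(ds.images))
        t = np.stack(ds.masks)[:, None].astype(np.float32)
        losses = []
        for _ in range(50):
            opt.zero_grad()
            loss = nn.bce_loss(net(x), t)
            losses.append(float(loss.data))
            loss.backward()
            opt.step()
        run = 0
        for prev, cur in zip(losses, losses[1:]):
            run = run + 1 if cur >= prev else 0
            assert run < 5, f"plateau of {run} steps in {losses}"
        assert losses[-1] < losses[0] / 2

    def test_same_seed_identical_traces(self, blob_dataset):
        ds, splits = blob_dataset
        cfg = TrainConfig(epochs=2, seed=11)
        r1 = train(_tiny_net(seed=3), splits, ds, cfg, folds=[0])
        r2 = train(_tiny_net(seed=3), splits, ds, cfg, folds=[0])
        assert r1.history[0]["loss"] == r2.history[0]["loss"]
        assert r1.history[0]["val_iou"] == r2.history[0]["val_iou"]

    def test_brief_training_beats_all_foreground_baseline(self, blob_dataset):
        """Learnability: even a tiny plain U-Net trained briefly on blobs
        clearly beats the trivial predict-everything-foreground baseline."""
        ds, splits = blob_dataset
        net = network_from_name("unet", seed=0, levels=3, base_width=8)
        res = train(net, splits, ds, TrainConfig(epochs=6, seed=2), folds=[0])
        iou_trained = evaluate(res.network, ds, splits.test_indices)["IoU"]
        truth = np.stack([ds.masks[i] for i in splits.test_indices])[:, None]
        baseline = iou(confusion_counts(np.ones_like(truth), truth))
        assert iou_trained > baseline + 0.1

    def test_empty_training_fold_rejected(self, blob_dataset):
        ds, _ = blob_dataset
        from msunet.synthetic import SplitPlan
        bad = SplitPlan(subset_of=np.ones(len(ds), dtype=int), test_subset=6,
                        folds=[(np.array([], dtype=int), np.array([0]))])
        with pytest.raises(ValueError, match="empty training fold"):
            train(_tiny_net(), bad, ds, TrainConfig(epochs=1), folds=[0])

    def test_divergence_aborts_with_diagnostic(self, blob_dataset):
        ds, splits = blob_dataset
        net = _tiny_net()
        for p in net.parameters():
            p.data[...] = np.nan
        with pytest.raises(RuntimeError, match="non-finite"):
            train(net, splits, ds, TrainConfig(epochs=1), folds=[0])


class TestEvaluate:
    def test_oracle_network_scores_perfectly(self, blob_dataset):
        ds, splits = blob_dataset

        class Oracle(nn.Module):
            def forward(self, x):
                i = Oracle.calls
                Oracle.calls += len(x.data)
                masks = np.stack(ds.masks[i:i + len(x.data)])[:, None]
                return nn.Tensor(masks.astype(np.float32))

        Oracle.calls = 0
        idx = np.arange(5)
        scores = evaluate(Oracle(), ds, idx)
        assert scores == {"IoU": 1.0, "Dice": 1.0, "Precision": 1.0, "AUC": 1.0}

    def test_constant_half_output_gives_half_auc(self, blob_dataset):
        ds, _ = blob_dataset

        class Half(nn.Module):
            def forward(self, x):
                return nn.Tensor(np.full((x.shape[0], 1) + x.shape[2:], 0.5,
                                         dtype=np.float32))

        scores = evaluate(Half(), ds, np.arange(4))
        assert scores["AUC"] == 0.5

    def test_matches_direct_metric_calls(self, blob_dataset):
        ds, splits = blob_dataset
        net = _tiny_net(seed=4)
        idx = splits.test_indices
        scores = evaluate(net, ds, idx, threshold=0.5)
        from msunet.training import _predict
        probs = _predict(net, ds, idx)
        truth = np.stack([ds.masks[i] for i in idx])[:, None]
        c = confusion_counts((probs >= 0.5).astype(np.uint8), truth)
        assert scores["IoU"] == iou(c)

    def test_empty_indices_rejected(self, blob_dataset):
        ds, _ = blob_dataset
        with pytest.raises(ValueError):
            evaluate(_tiny_net(), ds, np.array([], dtype=int))


class TestAblation:
    def test_rows_and_failures(self, tmp_path):
        cfg = TrainConfig(epochs=1, seed=0, batch_size=8)
        res = run_ablation(["unet", "nosuch_arch"], SyntheticStyle("blobs"), cfg,
                           seed=5, n_images=12, out_dir=tmp_path, folds=[0, 1],
                           **TINY)
        assert set(res.rows) == {"unet"}
        assert "nosuch_arch" in res.failures
        assert len(res.rows["unet"]["IoU"].values) == 2  # one per trained fold
        assert res.best == "unet"

    def test_resume_skips_completed_rows(self, tmp_path):
        cfg = TrainConfig(epochs=1, seed=0, batch_size=8)
        common = dict(style=SyntheticStyle("blobs"), cfg=cfg, seed=5,
                      n_images=12, out_dir=tmp_path, folds=[0], **TINY)
        r1 = run_ablation(["unet"], **common)
        saved = json.loads((tmp_path / "ablation.json").read_text())
        r2 = run_ablation(["unet", "msunet"], **common)
        assert r2.rows["unet"]["IoU"].values == r1.rows["unet"]["IoU"].values
        saved2 = json.loads((tmp_path / "ablation.json").read_text())
        assert saved["unet"] == saved2["unet"]

    def test_all31_name_list(self):
        names = all31_names()
        assert len(names) == 31 and "msunet:37" in names


class TestCompare:
    def test_annotates_higher_mean(self):
        out = compare([0.60, 0.62, 0.61], [0.70, 0.71, 0.69])
        assert out["better"] == "b" and out["p"] < 0.01

    def test_identical_fold_values(self):
        out = compare([0.5, 0.5], [0.5, 0.5])
        assert out["t"] == 0.0 and out["p"] == 1.0


class TestCLI:
    def test_synthesize_train_evaluate_pipeline(self, tmp_path):
        from click.testing import CliRunner
        from msunet.cli import main
        runner = CliRunner()
        data_dir = str(tmp_path / "data")
        r = runner.invoke(main, ["synthesize", "--style", "blobs", "--n", "12",
                                 "--seed", "1", "--out", data_dir])
        assert r.exit_code == 0, r.output
        ckpt = str(tmp_path / "net.npz")
        r = runner.invoke(main, ["train", "--arch", "unet", "--data", data_dir,
                                 "--epochs", "1", "--levels", "3",
                                 "--base-width", "4", "--out", ckpt])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, ["evaluate", "--checkpoint", ckpt, "--data",
                                 data_dir, "--roc-out", str(tmp_path / "roc.csv")])
        assert r.exit_code == 0, r.output
        assert "IoU" in r.output and (tmp_path / "roc.csv").exists()
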