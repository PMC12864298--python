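import numpy as np
import pytest

from dryshift import raster_prep, train_eval
from dryshift.train_eval import (
    MetricsReport,
    PatchSample,
    TrainConfig,
    assemble_ssl_dataset,
    evaluate_map,
    f1_from_iou,
    predict_map,
    train_model,
)
from dryshift.synthetic_scene import SyntheticSceneConfig, generate_label_map, render_scene
from dryshift.ynet_model import TrainLossSpec, YNetConfig, build_ynet

from conftest import make_raster


def _dummy_samples(n, side=8, n_classes=4, source="labeled", seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        out.append(
            PatchSample(
                optical=rng.random((6, side, side)),
                sar=rng.random((4, side // 2, side // 2)),
                labels=rng.integers(0, n_classes, (side, side)),
                source=source,
            )
        )
    return out


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

class TestAssembleSSL:
    def test_ratio_zero_all_labeled(self):
        labeled = _dummy_samples(20)
        out = assemble_ssl_dataset(labeled, _dummy_samples(50, source="pseudo"),
                                   mode="ratio", unlabeled_fraction=0.0)
        assert len(out) == 20
        assert all(s.source == "labeled" for s in out)

    def test_ratio_30_of_100(self):
        labeled = _dummy_samples(100)
        pseudo = _dummy_samples(100, source="pseudo", seed=1)
        out = assemble_ssl_dataset(labeled, pseudo, mode="ratio", unlabeled_fraction=0.3)
        assert len(out) == 100
        assert sum(s.source == "pseudo" for s in out) == 30
        assert sum(s.source == "labeled" for s in out) == 70

    def test_augment_561_plus_4470(self):
        labeled = _dummy_samples(561, side=2)
        pseudo = _dummy_samples(4470, side=2, source="pseudo", seed=1)
        out = assemble_ssl_dataset(labeled, pseudo, mode="augment", extra_count=4470)
        assert len(out) == 5031

    def test_ratio_size_constant_in_r(self):
        labeled = _dummy_samples(40)
        pseudo = _dummy_samples(60, source="pseudo", seed=1)
        sizes = {
            len(assemble_ssl_dataset(labeled, pseudo, mode="ratio", unlabeled_fraction=r))
            for r in (0.0, 0.2, 0.5, 0.9)
        }
        assert sizes == {40}

    def test_augment_strictly_increases(self):
        labeled = _dummy_samples(10)
        pseudo = _dummy_samples(30, source="pseudo", seed=1)
        n0 = len(labeled)
        for k in (1, 10, 30):
            assert len(assemble_ssl_dataset(labeled, pseudo, mode="augment", extra_count=k)) == n0 + k

    def test_out_of_range_ratio_rejected(self):
        with pytest.raises(ValueError):
            assemble_ssl_dataset(_dummy_samples(5), [], mode="ratio", unlabeled_fraction=0.95)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

class TestTrainModel:
    def _scene_samples(self, side=32, patch=16, noise=0.02, seed=0):
        cfg = SyntheticSceneConfig(height_px=side, width_px=side, optical_noise_sd=noise, seed=seed)
        lab = generate_label_map(cfg, seed)
        opt_r, sar_r = render_scene(lab, cfg, seed + 1)
        opt_r = raster_prep.compute_indices(opt_r)
        og, sg = opt_r.grid, sar_r.grid
        samples = []
        for r0 in range(0, side, patch):
            for c0 in range(0, side, patch):
                samples.append(
                    PatchSample(
                        optical=og[r0:r0 + patch, c0:c0 + patch].transpose(2, 0, 1),
                        sar=sg[r0 // 2:(r0 + patch) // 2, c0 // 2:(c0 + patch) // 2].transpose(2, 0, 1),
                        labels=lab.labels[r0:r0 + patch, c0:c0 + patch].astype(int),
                    )
                )
        return samples

    def test_overfit_single_batch(self):
        # standard overfit-one-batch sanity check: loss < 0.05 within 200 steps
        from dryshift.ynet_model import AdamW, jaccard_loss_from_logits

        samples = self._scene_samples(side=32, patch=32)
        model = build_ynet(YNetConfig(base_width=8, depth=2), seed=0)
        opt = AdamW(model.params(), lr=3e-3, weight_decay=0.0, no_decay=model.bn_params())
        spec = TrainLossSpec(ignore_class=None)
        o = np.stack([s.optical for s in samples])
        s = np.stack([s_.sar for s_ in samples])
        y = np.stack([s_.labels for s_ in samples])
        loss = None
        for _ in range(200):
            logits = model.forward(o, s, training=True)
            loss, d = jaccard_loss_from_logits(logits, y, spec)
            model.zero_grad()
            model.backward(d)
            opt.step()
        assert loss < 0.05

    def test_early_stopping_epoch_count(self, monkeypatch):
        # force a validation-loss sequence that improves once then stalls:
        # training must stop after exactly `patience` non-improving epochs
        samples = self._scene_samples()
        cfg = TrainConfig(max_epochs=50, batch_size=4, patience=3,
                          loss=TrainLossSpec(ignore_class=None), seed=0)
        forced = iter([0.5] + [0.6] * 49)
        monkeypatch.setattr(
            train_eval, "_eval_loss_and_metrics",
            lambda *a, **k: (next(forced), 0.0, 0.0),
        )
        model = build_ynet(YNetConfig(base_width=2, depth=2), seed=0)
        _, hist = train_model(model, samples[:3], samples[3:], cfg)
        assert len(hist) == 1 + cfg.patience
        assert hist.attrs["best_epoch"] == 0

    def test_deterministic_history(self):
        samples = self._scene_samples()
        tc = TrainConfig(max_epochs=3, batch_size=4, patience=2,
                         loss=TrainLossSpec(ignore_class=None), seed=42)
        hists = []
        for _ in range(2):
            model = build_ynet(YNetConfig(base_width=2, depth=2), seed=1)
            _, h = train_model(model, samples[:3], samples[3:], tc)
            hists.append(h)
        np.testing.assert_allclose(hists[0]["train_loss"], hists[1]["train_loss"])
        np.testing.assert_allclose(hists[0]["val_loss"], hists[1]["val_loss"])

    def test_empty_sets_rejected(self):
        model = build_ynet(YNetConfig(base_width=2, depth=2), seed=0)
        with pytest.raises(ValueError):
            train_model(model, [], _dummy_samples(2), TrainConfig(max_epochs=2, patience=1))


# ---------------------------------------------------------------------------
# prediction stitching
# ---------------------------------------------------------------------------

class _ConstantModel:
    """Stub predicting a fixed class everywhere."""

    def __init__(self, n_classes=6, cls=3):
        self.cls = cls
        self.config = YNetConfig(n_classes=n_classes, base_width=2, depth=2)

    def predict_proba(self, opt, sar):
        n, _, h, w = opt.shape
        probs = np.zeros((n, self.config.n_classes, h, w))
        probs[:, self.cls] = 1.0
        return probs


class TestPredictMap:
    def _scene(self, side=64):
        rng = np.random.default_rng(0)
        optical = make_raster(rng.random((side, side, 6)),
                              band_names=["Red", "Green", "Blue", "NIR", "NDVI", "GNDVI"])
        sar = make_raster(rng.random((side // 2, side // 2, 4)),
                          band_names=["HH", "HV", "VV", "VH"], pixel_size_m=10.0)
        return optical, sar

    def test_stitched_shape_matches_scene(self):
        optical, sar = self._scene()
        label_map, probs = predict_map(_ConstantModel(), optical, sar, optical_patch=32)
        assert label_map.labels.shape == (64, 64)
        assert probs.shape == (64, 64, 6)

    def test_constant_model_gives_constant_map(self):
        optical, sar = self._scene()
        label_map, _ = predict_map(_ConstantModel(cls=4), optical, sar, optical_patch=32)
        assert np.all(label_map.labels == 4)

    def test_stitching_matches_per_patch_oracle(self):
        optical, sar = self._scene(side=64)
        model = build_ynet(YNetConfig(base_width=2, depth=2), seed=0)
        label_map, probs = predict_map(model, optical, sar, optical_patch=32)
        # oracle: run each patch independently and reassemble by hand
        for r0 in (0, 32):
            for c0 in (0, 32):
                opt_p = optical.grid[r0:r0 + 32, c0:c0 + 32].transpose(2, 0, 1)[None]
                sar_p = sar.grid[r0 // 2:r0 // 2 + 16, c0 // 2:c0 // 2 + 16].transpose(2, 0, 1)[None]
                expected = model.predict_proba(opt_p, sar_p)[0].transpose(1, 2, 0)
                np.testing.assert_allclose(probs[r0:r0 + 32, c0:c0 + 32], expected)

    def test_scene_smaller_than_patch_rejected(self):
        optical, sar = self._scene(side=16)
        with pytest.raises(ValueError, match="smaller"):
            predict_map(_ConstantModel(), optical, sar, optical_patch=32)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

class TestEvaluateMap:
    def test_perfect_prediction(self, rng):
        truth = rng.integers(1, 5, (20, 20))
        rep = evaluate_map(truth, truth, ignore_class=0)
        assert rep.oa == 1.0 and rep.miou == 1.0

    def test_hand_computed_binary_counts(self):
        # TP=30, FP=10, FN=10, TN=50 for class 1 -> IoU 0.6, F1 0.75
        truth = np.array([1] * 40 + [0] * 60)
        pred = np.array([1] * 30 + [0] * 10 + [0] * 50 + [1] * 10)
        rep = evaluate_map(pred, truth, ignore_class=None)
        assert rep.iou[1] == pytest.approx(0.6)
        assert rep.f1[1] == pytest.approx(0.75)
        assert rep.oa == pytest.approx(0.8)

    def test_f1_iou_identity_per_class(self, rng):
        pred = rng.integers(0, 5, (30, 30))
        truth = rng.integers(0, 5, (30, 30))
        rep = evaluate_map(pred, truth, ignore_class=None)
        for c in rep.classes:
            assert rep.f1[c] == pytest.approx(f1_from_iou(rep.iou[c]), abs=5e-4)

    def test_reported_identity_pairs(self):
        # printed TDF pairs: IoU 0.778 -> F1 0.875, IoU 0.879 -> F1 0.936
        assert f1_from_iou(0.778) == pytest.approx(0.875, abs=5e-4)
        assert f1_from_iou(0.879) == pytest.approx(0.936, abs=5e-4)

    def test_confusion_rows_sum_to_100(self, rng):
        pred = rng.integers(0, 4, (25, 25))
        truth = rng.integers(0, 4, (25, 25))
        rep = evaluate_map(pred, truth, ignore_class=None)
        sums = rep.confusion_pct.sum(axis=1)
        present = rep.counts.sum(axis=1) > 0
        np.testing.assert_allclose(sums[present], 100.0, atol=0.1)

    def test_absent_class_excluded_with_warning(self):
        truth = np.array([[1, 1], [3, 3]])
        pred = np.array([[1, 1], [3, 3]])
        with pytest.warns(UserWarning, match="absent"):
            rep = evaluate_map(pred, truth, ignore_class=0)
        # class 2 appears in neither map and must be skipped, not zero-filled
        assert set(rep.classes) == {1, 3}
        assert rep.miou == 1.0

    def test_ignored_class_dropped_from_oa(self):
        truth = np.array([[0, 1], [1, 1]])
        pred = np.array([[1, 1], [1, 1]])  # wrong only on the ignored pixel
        rep = evaluate_map(pred, truth, ignore_class=0)
        assert rep.oa == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_map(np.zeros((2, 2), dtype=int), np.zeros((3, 3), dtype=int))


class TestSSLTrend:
    def test_ssl_at_30pct_loses_at_most_5_oa_points(self):
        # With accurate pseudo-labels, replacing 30% of the labeled training
        # set by pseudo-labeled patches must cost <= 5 OA points vs the fully
        # supervised run (fixed seed set, 3 repetitions).
        from dryshift.pseudolabel import (
            build_feature_table,
            fit_cluster_ensemble,
            fit_cluster_mappings,
            generate_pseudolabels,
        )
        from dryshift.synthetic_scene import generate_label_map, render_scene

        cfg = SyntheticSceneConfig(height_px=128, width_px=128, optical_noise_sd=0.02, seed=0)
        labels = generate_label_map(cfg, seed=0)
        optical, sar = render_scene(labels, cfg, seed=1)
        optical = raster_prep.compute_indices(optical)
        table = build_feature_table(optical, sar)
        ensemble = fit_cluster_ensemble(table, k=6, seed=0)
        fit_cluster_mappings(ensemble, table, labels.labels.ravel())
        pseudo_grid = generate_pseudolabels(ensemble, table)

        og = raster_prep.apply_normalization(optical, raster_prep.fit_normalization([optical.grid])).grid
        sg = raster_prep.apply_normalization(sar, raster_prep.fit_normalization([sar.grid])).grid

        def patch(r0, c0, size, label_grid):
            return PatchSample(
                optical=og[r0:r0 + size, c0:c0 + size].transpose(2, 0, 1),
                sar=sg[r0 // 2:(r0 + size) // 2, c0 // 2:(c0 + size) // 2].transpose(2, 0, 1),
                labels=label_grid[r0:r0 + size, c0:c0 + size].astype(int),
            )

        coords = [(r, c) for r in range(0, 128, 32) for c in range(0, 128, 32)]
        labeled = [patch(r, c, 32, labels.labels) for r, c in coords]
        pseudo = [
            PatchSample(optical=s.optical, sar=s.sar,
                        labels=pseudo_grid[r:r + 32, c:c + 32].astype(int), source="pseudo")
            for s, (r, c) in zip(labeled, coords)
        ]
        val, test = labeled[:2], labeled[2:6]
        pool = labeled[6:]
        pseudo_pool = pseudo[6:]

        def heldout_oa(train_set, seed):
            model = build_ynet(YNetConfig(base_width=8, depth=2), seed=seed)
            tc = TrainConfig(max_epochs=120, batch_size=5, peak_lr=3e-3, patience=25,
                             loss=TrainLossSpec(ignore_class=None), seed=seed)
            model, _ = train_model(model, train_set, val, tc)
            preds, trus = [], []
            for s in test:
                probs = model.predict_proba(s.optical[None], s.sar[None])[0]
                preds.append(probs.argmax(0).ravel())
                trus.append(s.labels.ravel())
            return evaluate_map(np.concatenate(preds), np.concatenate(trus),
                                ignore_class=None).oa

        # compare seed-matched runs averaged over the 3 repetitions: run-to-run
        # variance at this tiny scale exceeds the SSL effect itself
        base_oas, ssl_oas = [], []
        for rep in range(3):
            base_oas.append(heldout_oa(
                assemble_ssl_dataset(pool, pseudo_pool, "ratio", unlabeled_fraction=0.0, seed=rep),
                seed=rep,
            ))
            ssl_oas.append(heldout_oa(
                assemble_ssl_dataset(pool, pseudo_pool, "ratio", unlabeled_fraction=0.3, seed=rep),
                seed=rep,
            ))
        assert np.mean(ssl_oas) >= np.mean(base_oas) - 0.05


class TestTrainConfigValidation:
    def test_patience_must_be_less_than_epochs(self):
        with pytest.raises(ValueError):
            TrainConfig(max_epochs=5, patience=5)

    def test_defaults_match_training_protocol(self):
        cfg = TrainConfig()
        assert cfg.max_epochs == 300
        assert cfg.batch_size == 10
        assert cfg.weight_decay == pytest.approx(5e-4)
        assert cfg.peak_lr == pytest.approx(1.58e-4)
        assert cfg.patience == 10
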