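"""Training orchestration, evaluation metrics, baselines and embedding classifier."""

import numpy as np
import pytest

from trajsel.data import make_forecast_windows
from trajsel.errors import ConfigurationError
from trajsel.models import (
    ArchitectureSpec,
    EvalReport,
    TrainedModel,
    build_cnn1d,
    build_forecast_baselines,
    build_lstm_forecaster,
    classify_from_embeddings,
    evaluate,
    forecast_mse,
    load_trained,
    save_trained,
    train_classifier,
    train_forecaster,
    trajectory_embeddings,
)


def _auc_concordance_oracle(y, scores):
    """Brute-force pairwise concordance count (ties count half)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestEvaluate:
    def _trained_stub(self, probs, bundle):
        class _Fixed:
            def __init__(self, p):
                self.p = np.asarray(p, dtype=np.float32)

            def predict(self, x, batch_size=None):
                return self.p[: len(x), None]

        spec = ArchitectureSpec.default("cnn1d")
        return TrainedModel(spec=spec, model=_Fixed(probs), history={})

    def test_perfect_and_reversed_predictor(self, tiny_bundle):
        y = tiny_bundle.labels[tiny_bundle.indices("validation")]
        perfect = self._trained_stub(y.astype(float), tiny_bundle)
        rep = evaluate(perfect, tiny_bundle, "validation")
        assert rep.accuracy == 1.0 and rep.roc_auc == 1.0
        reversed_ = self._trained_stub(1.0 - y, tiny_bundle)
        rep2 = evaluate(reversed_, tiny_bundle, "validation")
        assert rep2.roc_auc == pytest.approx(1.0 - rep.roc_auc)

    def test_auc_matches_concordance_oracle(self, tiny_bundle, rng):
        y = tiny_bundle.labels[tiny_bundle.indices("validation")]
        probs = rng.random(len(y))
        rep = evaluate(self._trained_stub(probs, tiny_bundle), tiny_bundle, "validation")
        assert rep.roc_auc == pytest.approx(_auc_concordance_oracle(y, probs), abs=1e-12)

    def test_per_ligand_errors_sum_to_total(self, small_trained):
        trained, bundle = small_trained
        rep = evaluate(trained, bundle, "validation")
        total = rep.confusion["fp"] + rep.confusion["fn"]
        assert (
            rep.per_ligand.misclassified_reactive.sum()
            + rep.per_ligand.misclassified_nonreactive.sum()
            == total
        )
        assert 0.0 <= rep.accuracy <= 1.0

    def test_empty_split_raises(self, tiny_bundle):
        trained = self._trained_stub(np.zeros(4), tiny_bundle)
        bad = type(tiny_bundle)(
            tensors=tiny_bundle.tensors,
            labels=tiny_bundle.labels,
            ligand_ids=tiny_bundle.ligand_ids,
            enantiomers=tiny_bundle.enantiomers,
            descriptor_names=tiny_bundle.descriptor_names,
            units=tiny_bundle.units,
            train_idx=np.arange(tiny_bundle.n_trajectories),
            val_idx=np.array([], dtype=int),
            normalizer=tiny_bundle.normalizer,
        )
        with pytest.raises(ConfigurationError):
            evaluate(trained, bad, "validation")


class TestCapacity:
    def test_generalizes_to_held_out_ligands(self, small_trained):
        """Temporal class signal is recovered on unseen ligands."""
        trained, bundle = small_trained
        rep = evaluate(trained, bundle, "validation")
        assert rep.accuracy >= 0.85
        assert rep.roc_auc >= 0.9

    def test_null_labels_give_chance_level(self):
        from trajsel.data import default_split
        from trajsel.synthetic import GeneratorConfig, generate_null_dataset

        cfg = GeneratorConfig(n_ligands=6, n_per_class=25, n_frames=300, master_seed=13)
        nb = generate_null_dataset(cfg)
        default_split(nb)
        nb.fit_normalizer()
        model = build_cnn1d(nb.n_frames, nb.n_channels, seed=3)
        trained = train_classifier(model, nb, ArchitectureSpec.default("cnn1d", seed=3))
        rep = evaluate(trained, nb, "validation")
        assert abs(rep.accuracy - 0.5) <= 0.1


class TestForecasters:
    def test_baseline_predicts_last_value(self, rng):
        base = build_forecast_baselines(20, 4, query_channel=2)["baseline"]
        x = rng.random((6, 20, 4), dtype=np.float32)
        np.testing.assert_array_equal(base.predict(x)[:, 0], x[:, -1, 2])

    def test_baseline_zero_error_on_constant_series(self, tiny_bundle):
        ws = make_forecast_windows(tiny_bundle, stride=29)
        const = np.full_like(ws.inputs, 0.3)
        ws.inputs, ws.targets = const, np.full(len(ws), 0.3, dtype=np.float32)
        base = build_forecast_baselines(50, tiny_bundle.n_channels)["baseline"]
        assert forecast_mse(base, ws) == 0.0

    def test_linear_with_zero_weights_predicts_bias(self, rng):
        linear = build_forecast_baselines(20, 3)["linear"]
        linear.layers[1].params["W"][:] = 0.0
        linear.layers[1].params["b"][:] = 0.25
        x = rng.random((5, 20, 3), dtype=np.float32)
        np.testing.assert_allclose(linear.predict(x), 0.25, atol=1e-7)

    def test_all_baselines_train_on_same_interface(self, tiny_bundle):
        ws = make_forecast_windows(tiny_bundle, stride=29)
        models = build_forecast_baselines(50, tiny_bundle.n_channels, query_channel=3)
        for name, model in models.items():
            spec = ArchitectureSpec.default(name, seed=0, epochs=1)
            trained = train_forecaster(model, ws, spec)
            assert np.isfinite(forecast_mse(trained.model, ws))

    def test_lstm_beats_persistence_on_temporal_data(self):
        """With real temporal structure, the trained forecaster denoises better
        than predicting the last observed value (the ordering the simpler
        reference models are compared against)."""
        from trajsel.data import default_split
        from trajsel.synthetic import GeneratorConfig, generate_dataset

        cfg = GeneratorConfig(n_ligands=8, n_per_class=40, n_frames=300, master_seed=29)
        bundle = generate_dataset(cfg)
        default_split(bundle, 0.75)
        bundle.fit_normalizer()
        wtr = make_forecast_windows(bundle, stride=7, split="train")
        wva = make_forecast_windows(bundle, stride=7, split="validation")
        lstm = build_lstm_forecaster(50, bundle.n_channels, seed=2)
        trained = train_forecaster(
            lstm, wtr, ArchitectureSpec.default("lstm_forecaster", seed=2)
        )
        persistence = build_forecast_baselines(50, bundle.n_channels, query_channel=3)[
            "baseline"
        ]
        assert forecast_mse(trained.model, wva) < forecast_mse(persistence, wva)

    def test_window_shape_mismatch_raises(self, tiny_bundle):
        ws = make_forecast_windows(tiny_bundle, stride=29)
        model = build_lstm_forecaster(40, tiny_bundle.n_channels)
        with pytest.raises(ConfigurationError):
            train_forecaster(model, ws, ArchitectureSpec.default("lstm_forecaster"))

    def test_lstm_emits_scalar_and_8d_embedding(self, tiny_bundle):
        ws = make_forecast_windows(tiny_bundle, stride=29)
        model = build_lstm_forecaster(50, tiny_bundle.n_channels, seed=0)
        spec = ArchitectureSpec.default("lstm_forecaster", seed=0, epochs=1)
        trained = train_forecaster(model, ws, spec)
        pred = trained.model.predict(ws.inputs[:5])
        assert pred.shape == (5, 1)
        emb, labels = trajectory_embeddings(trained, ws)
        assert emb.shape == (tiny_bundle.n_trajectories, 8)
        assert len(labels) == len(emb)


class TestEmbeddingClassifier:
    def test_separable_clusters_reach_perfect_accuracy(self, rng):
        emb = np.concatenate([rng.normal(-3, 0.1, (40, 8)), rng.normal(3, 0.1, (40, 8))])
        y = np.repeat([0, 1], 40)
        _, rep = classify_from_embeddings(emb, y, seed=0)
        assert rep["accuracy"] == 1.0

    def test_constant_embeddings_stay_at_chance(self):
        emb = np.zeros((60, 8))
        y = np.repeat([0, 1], 30)
        _, rep = classify_from_embeddings(emb, y, seed=0)
        assert abs(rep["accuracy"] - 0.5) <= 0.05
        assert rep["loss"] == pytest.approx(np.log(2), abs=0.02)

    def test_count_mismatch_raises(self):
        with pytest.raises(ConfigurationError):
            classify_from_embeddings(np.zeros((5, 8)), np.zeros(4))


class TestPersistence:
    def test_checkpoint_roundtrip(self, small_trained, tmp_path):
        trained, bundle = small_trained
        path = tmp_path / "model.npz"
        save_trained(path, trained)
        back = load_trained(path)
        x = bundle.normalized("validation")[:8].astype(np.float32)
        np.testing.assert_allclose(
            back.predict_proba(x), trained.predict_proba(x), atol=1e-6
        )
        assert back.spec == trained.spec
        np.testing.assert_allclose(back.normalizer.offset, trained.normalizer.offset)
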