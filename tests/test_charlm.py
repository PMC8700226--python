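"""The character LSTM language model and fine-tuned classifier."""

import numpy as np
import pytest

from takeaway_cuisine import charlm
from takeaway_cuisine.charlm import (
    CharLMClassifier,
    TrainConfig,
    fine_tune_classifier,
    lm_cross_entropy,
    load_model,
    predict,
    predict_batch,
    save_model,
    train_char_lm,
)
from takeaway_cuisine.records import LabeledOutlet, OutletRecord
from takeaway_cuisine.split import SplitSet
from takeaway_cuisine.textprep import build_vocabulary

TINY = TrainConfig(embedding_dim=12, hidden_dim=24, n_layers=1,
                   max_epochs=3, patience=3, batch_size=16, seed=0)


class TestTrainConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(dropout=1.0)
        with pytest.raises(ValueError):
            TrainConfig(patience=20, max_epochs=5)
        with pytest.raises(ValueError):
            TrainConfig(lr_schedule="cosine")
        with pytest.raises(ValueError):
            TrainConfig(hidden_dim=0)


class TestLanguageModel:
    def test_near_deterministic_corpus_reaches_low_entropy(self):
        """A corpus of one repeated name is almost perfectly predictable:
        held-out cross-entropy far below the uniform baseline ln(V)."""
        names = ["pizza pizza"] * 64
        vocab = build_vocabulary(names)
        config = TrainConfig(embedding_dim=12, hidden_dim=24, n_layers=1,
                             max_epochs=30, patience=30, batch_size=16, seed=1)
        encoder = train_char_lm(names, vocab, config)
        ce = lm_cross_entropy(encoder, ["pizza pizza"])
        assert ce < 0.5  # nats; ln(V) ~ 2.5

    def test_random_corpus_stays_at_uniform_baseline(self):
        """Uniform random characters carry no structure: cross-entropy
        converges to ln(V) and cannot go meaningfully below it."""
        rng = np.random.default_rng(2)
        alphabet = list("abcdefgh")
        # long names keep the (learnable) end-of-name transition a
        # negligible share of the per-token average
        names = ["".join(rng.choice(alphabet, size=30)) for _ in range(300)]
        vocab = build_vocabulary(names)
        config = TrainConfig(embedding_dim=12, hidden_dim=24, n_layers=1,
                             max_epochs=8, patience=8, batch_size=32, seed=3)
        encoder = train_char_lm(names, vocab, config)
        held_out = ["".join(rng.choice(alphabet, size=30)) for _ in range(100)]
        ce = lm_cross_entropy(encoder, held_out)
        # only the character identities (8 of them) are unpredictable;
        # the bos/eos structure is learnable, so compare on ln(8)
        assert ce == pytest.approx(np.log(len(alphabet)), rel=0.05)

    def test_seeded_determinism(self):
        names = ["golden wok", "ocean fry", "pizza palace"] * 8
        vocab = build_vocabulary(names)
        one = train_char_lm(names, vocab, TINY)
        two = train_char_lm(names, vocab, TINY)
        assert one.training_log == two.training_log
        for k, v in one.net.params.items():
            assert np.array_equal(v, two.net.params[k])

    def test_training_loss_decreases_initially(self):
        names = ["golden wok", "ocean fry", "pizza palace", "kebab house"] * 16
        vocab = build_vocabulary(names)
        config = TrainConfig(embedding_dim=12, hidden_dim=24, n_layers=1,
                             max_epochs=4, patience=4, batch_size=16, seed=4)
        encoder = train_char_lm(names, vocab, config)
        losses = [e["lm_loss"] for e in encoder.training_log]
        assert losses[-1] < losses[0]

    def test_empty_corpus_rejected(self):
        vocab = build_vocabulary(["x"])
        with pytest.raises(ValueError):
            train_char_lm([], vocab, TINY)

    def test_init_vocab_mismatch_rejected(self):
        names = ["ab"] * 4
        vocab = build_vocabulary(names)
        encoder = train_char_lm(names, vocab, TINY)
        other_vocab = build_vocabulary(["xyz"])
        with pytest.raises(ValueError, match="vocab"):
            train_char_lm(["xyz"] * 4, other_vocab, TINY, init=encoder)

    def test_warm_start_from_supplied_encoder(self):
        names = ["golden wok", "ocean fry"] * 8
        vocab = build_vocabulary(names)
        encoder = train_char_lm(names, vocab, TINY)
        resumed = train_char_lm(names, vocab, TINY, init=encoder)
        assert resumed.training_log[0]["lm_loss"] < 1.5 * \
            encoder.training_log[-1]["lm_loss"]


class TestClassifier:
    def test_validation_class_missing_from_training(self, tiny_model, tiny_split):
        extra = SplitSet(
            train_unique=tiny_split.train_unique,
            validation=[LabeledOutlet(OutletRecord(name="x"), "martian", "owner_label")],
        )
        with pytest.raises(ValueError, match="martian"):
            fine_tune_classifier(tiny_model.encoder, extra,
                                 tiny_model.encoder.config)

    def test_separable_corpus_high_recall(self, tiny_model, tiny_split):
        from takeaway_cuisine.evaluate import evaluate_predictions

        preds = predict_batch(tiny_model, [l.record for l in tiny_split.validation])
        report = evaluate_predictions(
            [l.cuisine for l in tiny_split.validation],
            [p.cuisine for _, p in preds],
            sorted(tiny_model.classes),
        )
        assert report.macro_recall >= 0.9

    def test_early_stopping_keeps_best_epoch(self, tiny_model):
        log = tiny_model.training_log
        best = max(e["val_accuracy"] for e in log)
        last_improvement = max(i for i, e in enumerate(log)
                               if e["val_accuracy"] == best)
        # training continued at most `patience` epochs past the best one
        assert len(log) - 1 - last_improvement <= tiny_model.encoder.config.patience


class TestPrediction:
    def test_distribution_invariants(self, tiny_model):
        p = predict(tiny_model, "pizza palace")
        assert sum(p.distribution.values()) == pytest.approx(1.0, abs=1e-6)
        assert p.confidence == pytest.approx(max(p.distribution.values()))
        assert p.cuisine == max(p.distribution, key=p.distribution.get)

    def test_separable_name_classified_correctly(self, tiny_model, tiny_corpus):
        config = tiny_corpus.config
        for cls, pool in zip(config.classes, config.vocab_per_class):
            name = " ".join(pool[:2])
            assert predict(tiny_model, name).cuisine == cls

    def test_repeat_calls_identical(self, tiny_model):
        a = predict(tiny_model, "golden wok")
        b = predict(tiny_model, "golden wok")
        assert a == b

    def test_empty_name_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            predict(tiny_model, "")

    def test_batch_matches_elementwise(self, tiny_model):
        records = [OutletRecord(name=n) for n in
                   ["golden wok", "pizza palace", "ocean fry"]]
        batch = predict_batch(tiny_model, records)
        assert [r.name for r, _ in batch] == [r.name for r in records]
        for record, pred in batch:
            solo = predict(tiny_model, record.name)
            assert solo.cuisine == pred.cuisine
            assert solo.confidence == pytest.approx(pred.confidence, abs=1e-6)

    def test_empty_batch(self, tiny_model):
        assert predict_batch(tiny_model, []) == []


class TestSerialization:
    def test_round_trip_identical_predictions(self, tiny_model, tmp_path):
        path = tmp_path / "model.npz"
        save_model(tiny_model, path)
        loaded = load_model(path)
        probe = ["golden wok", "pizza palace", "mystery shack"]
        for name in probe:
            a, b = predict(tiny_model, name), predict(loaded, name)
            assert a.cuisine == b.cuisine
            assert a.distribution == pytest.approx(b.distribution)
        assert loaded.classes == tiny_model.classes
        assert loaded.encoder.config == tiny_model.encoder.config


class TestSklearnEstimator:
    @pytest.fixture(scope="class")
    def fitted(self, tiny_corpus):
        from takeaway_cuisine.textprep import normalize_name

        names = [normalize_name(r.name) for r in tiny_corpus.records]
        clf = CharLMClassifier(embedding_dim=16, hidden_dim=48, n_layers=1,
                               lm_epochs=4, max_epochs=15, patience=5,
                               random_state=0)
        return clf.fit(names, tiny_corpus.truth), names, tiny_corpus.truth

    def test_predict_proba_shape_and_norm(self, fitted):
        clf, names, truth = fitted
        proba = clf.predict_proba(names[:10])
        assert proba.shape == (10, len(clf.classes_))
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_learns_the_separable_corpus(self, fitted):
        clf, names, truth = fitted
        assert clf.score(names, truth) >= 0.9

    def test_clonable_with_params(self):
        from sklearn.base import clone

        clf = CharLMClassifier(hidden_dim=48, gradual_unfreeze=True)
        cloned = clone(clf)
        assert cloned.hidden_dim == 48 and cloned.gradual_unfreeze

    def test_unfitted_raises(self):
        with pytest.raises(ValueError):
            CharLMClassifier().predict(["x"])
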