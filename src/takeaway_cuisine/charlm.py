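"""Character-level language-model classifier.

The model follows the universal language-model fine-tuning recipe adapted
to characters: first an LSTM is trained on the entire corpus of business
names with a next-character objective (names are far too short, and their
word vocabulary far too sparse, for a word-level model); the encoder is
then given a concat-pooled softmax classification head and fine-tuned on
the balanced labelled training set, with early stopping on validation
accuracy.  General-corpus pretraining is optional: by default the encoder
is trained from scratch on the name corpus, or it can be initialised from
a previously saved :class:`EncoderState`.

Two interfaces are provided: a functional one (:func:`train_char_lm`,
:func:`fine_tune_classifier`, :func:`predict`) mirroring the pipeline
stages, and :class:`CharLMClassifier`, a scikit-learn estimator wrapping
the whole recipe behind ``fit`` / ``predict`` / ``predict_proba``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._nn import Adam, CharRNN, pad_batch, softmax
from .records import LabeledOutlet, OutletRecord
from .split import SplitSet
from .textprep import CharVocabulary, build_vocabulary, normalize_name, tokenize_chars

__all__ = [
    "TrainConfig",
    "EncoderState",
    "ClassifierModel",
    "Prediction",
    "train_char_lm",
    "lm_cross_entropy",
    "fine_tune_classifier",
    "predict",
    "predict_batch",
    "save_model",
    "load_model",
    "CharLMClassifier",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters for language-model training and classifier
    fine-tuning.  Defaults are sized for CPU training on corpora of a few
    thousand short names."""

    embedding_dim: int = 32
    hidden_dim: int = 128
    n_layers: int = 2
    dropout: float = 0.2
    batch_size: int = 64
    max_epochs: int = 12
    patience: int = 3
    learning_rate: float = 3e-3
    lr_schedule: str = "constant"  # or "slanted_triangular"
    gradual_unfreeze: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("embedding_dim", "hidden_dim", "n_layers", "batch_size",
                     "max_epochs", "patience"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience > self.max_epochs:
            raise ValueError("patience cannot exceed max_epochs")
        if self.lr_schedule not in ("constant", "slanted_triangular"):
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")


@dataclass
class EncoderState:
    """A trained character LSTM encoder plus its vocabulary, configuration
    and per-epoch training log."""

    vocab: CharVocabulary
    net: CharRNN
    config: TrainConfig
    training_log: list[dict] = field(default_factory=list)


@dataclass
class ClassifierModel:
    """Encoder + classification head + ordered class list."""

    encoder: EncoderState
    classes: tuple[str, ...]
    training_log: list[dict] = field(default_factory=list)

    @property
    def vocab(self) -> CharVocabulary:
        return self.encoder.vocab


@dataclass(frozen=True)
class Prediction:
    """One classification: the argmax class, its probability, and the full
    distribution over classes."""

    cuisine: str
    confidence: float
    distribution: dict[str, float]


def _slanted_triangular(step: int, total: int, lr_max: float,
                        cut_frac: float = 0.1, ratio: float = 32.0) -> float:
    cut = max(1, int(total * cut_frac))
    if step < cut:
        p = step / cut
    else:
        p = max(0.0, 1.0 - (step - cut) / max(1, total - cut))
    return lr_max * (1.0 + p * (ratio - 1.0)) / ratio


def _lr_at(config: TrainConfig, step: int, total: int) -> float:
    if config.lr_schedule == "slanted_triangular":
        return _slanted_triangular(step, total, config.learning_rate)
    return config.learning_rate


def train_char_lm(
    names: Sequence[str],
    vocab: CharVocabulary,
    config: TrainConfig,
    init: Optional[EncoderState] = None,
) -> EncoderState:
    """Train the next-character language model on ``names``.

    ``init`` optionally supplies pretrained encoder weights (its vocabulary
    must match).  Training minimises mean next-character cross-entropy by
    Adam for ``config.max_epochs`` epochs; the per-epoch mean training loss
    is recorded in the returned state's ``training_log``.  Reproducible for
    a fixed ``config.seed``.
    """
    names = list(names)
    if not names:
        raise ValueError("cannot train a language model on an empty corpus")
    rng = np.random.default_rng(config.seed)
    if init is not None:
        if init.vocab.tokens != vocab.tokens:
            raise ValueError("init encoder vocabulary does not match the corpus vocabulary")
        net = CharRNN(vocab.size, config.embedding_dim, config.hidden_dim,
                      config.n_layers, None, rng)
        for k in net.encoder_param_names() + ["lm_W", "lm_b"]:
            if k in init.net.params:
                net.params[k] = init.net.params[k].copy()
    else:
        net = CharRNN(vocab.size, config.embedding_dim, config.hidden_dim,
                      config.n_layers, None, rng)

    seqs = [tokenize_chars(n, vocab) for n in names]
    opt = Adam(net.params, lr=config.learning_rate)
    n_batches = int(np.ceil(len(seqs) / config.batch_size))
    total_steps = config.max_epochs * n_batches
    log: list[dict] = []
    step = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(seqs))
        losses = []
        for b in range(n_batches):
            batch = [seqs[i] for i in order[b * config.batch_size:(b + 1) * config.batch_size]]
            ids, _ = pad_batch(batch, vocab.pad_id)
            loss, grads = net.lm_loss_and_grads(
                ids, None, vocab.pad_id, dropout=config.dropout, rng=rng
            )
            opt.step(net.params, grads, lr=_lr_at(config, step, total_steps))
            losses.append(loss)
            step += 1
        log.append({"epoch": epoch, "lm_loss": float(np.mean(losses))})
    return EncoderState(vocab=vocab, net=net, config=config, training_log=log)


def lm_cross_entropy(encoder: EncoderState, names: Sequence[str]) -> float:
    """Mean held-out next-character cross-entropy (nats) of the language
    model on ``names``.  The uniform-baseline reference is ``ln(V)``."""
    names = list(names)
    if not names:
        raise ValueError("no names to evaluate")
    vocab = encoder.vocab
    total, n_tok = 0.0, 0
    bs = encoder.config.batch_size
    seqs = [tokenize_chars(n, vocab) for n in names]
    for b in range(0, len(seqs), bs):
        ids, _ = pad_batch(seqs[b:b + bs], vocab.pad_id)
        loss, _ = encoder.net.lm_loss_and_grads(ids, None, vocab.pad_id, backward=False)
        k = int((ids[:, 1:] != vocab.pad_id).sum())
        total += loss * k
        n_tok += k
    return total / n_tok


def _encode_names(names: Sequence[str], vocab: CharVocabulary):
    seqs = [tokenize_chars(n, vocab) for n in names]
    return pad_batch(seqs, vocab.pad_id)


def _accuracy(net: CharRNN, names: Sequence[str], y: np.ndarray,
              vocab: CharVocabulary, batch_size: int) -> float:
    correct = 0
    for b in range(0, len(names), batch_size):
        ids, lengths = _encode_names(names[b:b + batch_size], vocab)
        proba = net.predict_proba(ids, lengths)
        correct += int((proba.argmax(axis=1) == y[b:b + batch_size]).sum())
    return correct / len(names)


def fine_tune_classifier(
    encoder: EncoderState,
    split: SplitSet,
    config: TrainConfig,
) -> ClassifierModel:
    """Fine-tune a classification head (and the encoder) on the balanced
    training set, early-stopping on validation accuracy.

    The returned model carries the weights of the epoch with the best
    validation accuracy.  With ``config.gradual_unfreeze`` the first epoch
    trains the head only, the second adds the top LSTM layer, and later
    epochs train everything.
    """
    train = split.train_balanced or split.train_unique
    if not train:
        raise ValueError("split has no training records")
    classes = tuple(sorted({r.cuisine for r in train}))
    val_classes = {r.cuisine for r in split.validation}
    missing = val_classes - set(classes)
    if missing:
        raise ValueError(
            f"classes {sorted(missing)} present in validation but absent from training"
        )
    class_index = {c: i for i, c in enumerate(classes)}

    rng = np.random.default_rng(config.seed)
    # architecture is fixed by the trained encoder
    net = CharRNN(encoder.vocab.size, encoder.net.embedding_dim,
                  encoder.net.hidden_dim, encoder.net.n_layers, None, rng)
    for k in net.encoder_param_names():
        net.params[k] = encoder.net.params[k].copy()
    net.params["lm_W"] = encoder.net.params["lm_W"].copy()
    net.params["lm_b"] = encoder.net.params["lm_b"].copy()
    net.add_head(len(classes), rng)

    vocab = encoder.vocab
    names = [r.name for r in train]
    y = np.array([class_index[r.cuisine] for r in train], dtype=np.int64)
    val_names = [r.name for r in split.validation]
    y_val = np.array([class_index[r.cuisine] for r in split.validation], dtype=np.int64)

    seqs = [tokenize_chars(n, vocab) for n in names]
    opt = Adam(net.params, lr=config.learning_rate)
    n_batches = int(np.ceil(len(seqs) / config.batch_size))
    total_steps = config.max_epochs * n_batches

    encoder_params = set(net.encoder_param_names())
    top = net.n_layers - 1
    top_layer = {f"Wx{top}", f"Wh{top}", f"b{top}"}

    best_acc = -1.0
    best_params = net.copy_params()
    best_epoch = -1
    log: list[dict] = []
    step = 0
    for epoch in range(config.max_epochs):
        if config.gradual_unfreeze:
            if epoch == 0:
                frozen = encoder_params | {"lm_W", "lm_b"}
            elif epoch == 1:
                frozen = (encoder_params - top_layer) | {"lm_W", "lm_b"}
            else:
                frozen = {"lm_W", "lm_b"}
        else:
            frozen = {"lm_W", "lm_b"}
        order = rng.permutation(len(seqs))
        losses = []
        for b in range(n_batches):
            take = order[b * config.batch_size:(b + 1) * config.batch_size]
            batch = [seqs[i] for i in take]
            ids, lengths = pad_batch(batch, vocab.pad_id)
            loss, grads = net.clf_loss_and_grads(
                ids, lengths, y[take], dropout=config.dropout, rng=rng
            )
            opt.step(net.params, grads, lr=_lr_at(config, step, total_steps), frozen=frozen)
            losses.append(loss)
            step += 1
        val_acc = _accuracy(net, val_names, y_val, vocab, config.batch_size) \
            if val_names else float("nan")
        log.append({"epoch": epoch, "clf_loss": float(np.mean(losses)),
                    "val_accuracy": val_acc})
        if val_names:
            if val_acc > best_acc:
                best_acc = val_acc
                best_params = net.copy_params()
                best_epoch = epoch
            elif epoch - best_epoch >= config.patience:
                break
        else:
            best_params = net.copy_params()
    net.set_params_(best_params)
    tuned = EncoderState(vocab=vocab, net=net, config=config,
                         training_log=encoder.training_log)
    return ClassifierModel(encoder=tuned, classes=classes, training_log=log)


def predict(model: ClassifierModel, name: str) -> Prediction:
    """Classify one (normalised) business name."""
    if not name:
        raise ValueError("cannot classify an empty name")
    return predict_batch(model, [OutletRecord(name=name)])[0][1]


def predict_batch(
    model: ClassifierModel, records: Sequence[OutletRecord]
) -> list[tuple[OutletRecord, Prediction]]:
    """Element-wise :func:`predict` over ``records``, order preserved."""
    if not records:
        return []
    for rec in records:
        if not rec.name:
            raise ValueError(f"record {rec.record_id!r} has an empty name")
    net = model.encoder.net
    vocab = model.vocab
    bs = model.encoder.config.batch_size
    out: list[tuple[OutletRecord, Prediction]] = []
    for b in range(0, len(records), bs):
        chunk = records[b:b + bs]
        ids, lengths = _encode_names([r.name for r in chunk], vocab)
        proba = net.predict_proba(ids, lengths)
        for rec, row in zip(chunk, proba):
            k = int(row.argmax())
            out.append(
                (rec, Prediction(
                    cuisine=model.classes[k],
                    confidence=float(row[k]),
                    distribution={c: float(p) for c, p in zip(model.classes, row)},
                ))
            )
    return out


# --------------------------------------------------------------------- #
# serialization: a single .npz container with weights + JSON metadata

def save_model(model: ClassifierModel, path) -> None:
    meta = {
        "vocab_tokens": list(model.vocab.tokens),
        "classes": list(model.classes),
        "config": asdict(model.encoder.config),
        "training_log": model.training_log,
        "lm_log": model.encoder.training_log,
    }
    arrays = {f"param_{k}": v for k, v in model.encoder.net.params.items()}
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)


def load_model(path) -> ClassifierModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        params = {k[len("param_"):]: data[k] for k in data.files if k.startswith("param_")}
    tokens = tuple(meta["vocab_tokens"])
    vocab = CharVocabulary(tokens=tokens, index={t: i for i, t in enumerate(tokens)})
    config = TrainConfig(**meta["config"])
    rng = np.random.default_rng(0)
    net = CharRNN(vocab.size, config.embedding_dim, config.hidden_dim,
                  config.n_layers, len(meta["classes"]), rng)
    net.params = params
    encoder = EncoderState(vocab=vocab, net=net, config=config,
                           training_log=meta["lm_log"])
    return ClassifierModel(encoder=encoder, classes=tuple(meta["classes"]),
                           training_log=meta["training_log"])


# --------------------------------------------------------------------- #
# scikit-learn estimator

class CharLMClassifier(ClassifierMixin, BaseEstimator):
    """Character-level LSTM cuisine classifier with language-model
    pretraining, as a scikit-learn estimator.

    ``fit(X, y)`` takes raw business names and their classes; names are
    normalised internally.  The encoder is first trained as a
    next-character language model on ``lm_corpus`` (if given) plus the
    training names, then fine-tuned with a classification head, early
    stopping on a held-out validation sample.

    Parameters mirror :class:`TrainConfig`; ``lm_epochs`` controls the
    language-model stage and ``max_epochs`` the fine-tuning stage.
    ``validation_fraction`` is carved from the training data when no
    explicit validation set is passed to ``fit``.
    """

    def __init__(self, embedding_dim: int = 32, hidden_dim: int = 128,
                 n_layers: int = 2, dropout: float = 0.2, batch_size: int = 64,
                 lm_epochs: int = 3, max_epochs: int = 12, patience: int = 3,
                 learning_rate: float = 3e-3, lr_schedule: str = "constant",
                 gradual_unfreeze: bool = False, validation_fraction: float = 0.1,
                 random_state: int = 0):
        self.embedding_dim = embedding_dim
        self.hidden_dim = hidden_dim
        self.n_layers = n_layers
        self.dropout = dropout
        self.batch_size = batch_size
        self.lm_epochs = lm_epochs
        self.max_epochs = max_epochs
        self.patience = patience
        self.learning_rate = learning_rate
        self.lr_schedule = lr_schedule
        self.gradual_unfreeze = gradual_unfreeze
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _config(self, max_epochs: int) -> TrainConfig:
        return TrainConfig(
            embedding_dim=self.embedding_dim, hidden_dim=self.hidden_dim,
            n_layers=self.n_layers, dropout=self.dropout,
            batch_size=self.batch_size, max_epochs=max_epochs,
            patience=min(self.patience, max_epochs),
            learning_rate=self.learning_rate, lr_schedule=self.lr_schedule,
            gradual_unfreeze=self.gradual_unfreeze, seed=self.random_state,
        )

    def fit(self, X, y, lm_corpus: Optional[Iterable[str]] = None,
            X_val=None, y_val=None):
        names = [normalize_name(str(x), allow_empty=False) for x in X]
        y = np.asarray(y)
        if len(names) != len(y):
            raise ValueError("X and y have different lengths")
        self.classes_ = np.unique(y)

        lm_names = list(names)
        if lm_corpus is not None:
            lm_names += [normalize_name(str(x)) for x in lm_corpus]
        if X_val is not None:
            val_names = [normalize_name(str(x), allow_empty=False) for x in X_val]
            lm_names += val_names
        vocab = build_vocabulary(lm_names)

        lm_config = self._config(self.lm_epochs)
        self.encoder_ = train_char_lm(lm_names, vocab, lm_config)

        if X_val is None:
            train_outlets, val_outlets = self._carve_validation(names, y)
        else:
            train_outlets = [
                LabeledOutlet(OutletRecord(name=n), str(c), "owner_label")
                for n, c in zip(names, y)
            ]
            val_outlets = [
                LabeledOutlet(OutletRecord(name=n), str(c), "owner_label")
                for n, c in zip(val_names, np.asarray(y_val))
            ]
        split = SplitSet(train_unique=train_outlets, validation=val_outlets,
                         seed=self.random_state)
        self.model_ = fine_tune_classifier(self.encoder_, split,
                                           self._config(self.max_epochs))
        self.history_ = {"lm": self.encoder_.training_log,
                         "classifier": self.model_.training_log}
        return self

    def _carve_validation(self, names, y):
        rng = np.random.default_rng(self.random_state)
        train_outlets, val_outlets = [], []
        for cls in self.classes_:
            idx = np.flatnonzero(y == cls)
            n_val = max(1, int(round(self.validation_fraction * len(idx)))) \
                if len(idx) > 1 else 0
            chosen = set(rng.choice(idx, size=n_val, replace=False).tolist())
            for i in idx:
                outlet = LabeledOutlet(OutletRecord(name=names[i]), str(cls),
                                       "owner_label")
                (val_outlets if i in chosen else train_outlets).append(outlet)
        return train_outlets, val_outlets

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        names = [normalize_name(str(x), allow_empty=False) for x in X]
        preds = predict_batch(self.model_, [OutletRecord(name=n) for n in names])
        order = {c: i for i, c in enumerate(self.model_.classes)}
        proba = np.array(
            [[p.distribution[c] for c in self.model_.classes] for _, p in preds]
        )
        # column order must follow classes_
        cols = [order[str(c)] for c in self.classes_]
        return proba[:, cols]

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)]

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise ValueError("this CharLMClassifier instance is not fitted yet")
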