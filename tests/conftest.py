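"""Shared fixtures: small synthetic corpora and a cheaply trained model."""

import pytest

from takeaway_cuisine import charlm, dedup, synth, textprep
from takeaway_cuisine.labeler import assign_all, default_scheme
from takeaway_cuisine.records import UNCLASSIFIED
from takeaway_cuisine.split import balance_train, make_split

TINY_CLASSES = ("pizza", "desserts", "fish_and_chips")


def run_pipeline(config, n_val_per_class, balance_target, seed):
    """clean -> dedup -> label -> split -> balance on a synthetic corpus."""
    corpus = synth.generate_corpus(config)
    records = [r.with_name(textprep.normalize_name(r.name)) for r in corpus.records]
    unique = dedup.deduplicate(dedup.group_duplicates(records))
    labeled = [
        l for l in assign_all(unique, default_scheme()) if l.cuisine != UNCLASSIFIED
    ]
    split = make_split(labeled, n_val_per_class=n_val_per_class, seed=seed)
    balance_train(split, balance_target, seed=seed + 1)
    return corpus, labeled, split


@pytest.fixture(scope="session")
def tiny_corpus():
    """Small separable 3-class corpus for fast classifier tests."""
    config = synth.separable_config(
        seed=7, n_per_class=120, classes=TINY_CLASSES,
        chain_rate=0.0, duplicate_rate=0.0,
    )
    return synth.generate_corpus(config)


@pytest.fixture(scope="session")
def tiny_split(tiny_corpus):
    records = [
        r.with_name(textprep.normalize_name(r.name)) for r in tiny_corpus.records
    ]
    labeled = [
        l for l in assign_all(records, default_scheme()) if l.cuisine != UNCLASSIFIED
    ]
    split = make_split(labeled, n_val_per_class=30, seed=8)
    balance_train(split, 240, seed=9)
    return split


@pytest.fixture(scope="session")
def tiny_model(tiny_split):
    """A small classifier trained on the tiny separable corpus."""
    names = [l.name for l in tiny_split.train_unique + tiny_split.validation]
    vocab = textprep.build_vocabulary(names)
    lm_config = charlm.TrainConfig(
        embedding_dim=16, hidden_dim=48, n_layers=1, max_epochs=4, patience=4, seed=10
    )
    encoder = charlm.train_char_lm(names, vocab, lm_config)
    clf_config = charlm.TrainConfig(
        embedding_dim=16, hidden_dim=48, n_layers=1, max_epochs=15, patience=5, seed=11
    )
    return charlm.fine_tune_classifier(encoder, tiny_split, clf_config)
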