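"""Synthetic outlet-name corpora with known ground truth.

The real training data (owner-labelled takeaway listings from an online
ordering platform) cannot be redistributed, so every downstream stage is
exercised on generated corpora that emulate its statistical structure:

* short names (1-5 words) built from pronounceable synthetic words;
* class-specific vocabulary mixed with generic shared words, with a
  tunable ``signal_strength``;
* chain outlets repeated with location suffixes (" - <place>" or
  "(<place>)"), exact duplicates, accented characters, and noisy
  owner labels;
* an optional *subword* mode in which the class signal is a 3-character
  affix implanted inside otherwise generic words — visible to a
  character-level model but not to whole-word scoring.

Word pools, place names and affixes are generated from syllables under a
fixed internal seed, so the default conditions are stable across runs;
corpus sampling itself is driven by ``SynthConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import OutletRecord

__all__ = [
    "SynthConfig",
    "SynthCorpus",
    "generate_corpus",
    "default_config",
    "separable_config",
    "zero_signal_config",
    "subword_config",
    "write_corpus_csv",
    "write_truth_csv",
    "write_population_csv",
]

# Class identifiers mirror the 10-point cuisine scheme so owner labels map
# through the default scheme unchanged.
DEFAULT_CLASSES = (
    "chicken",
    "kebab",
    "pizza",
    "burger",
    "multi_fast_food",
    "desserts",
    "sandwich_cafe_bakery",
    "fish_and_chips",
    "south_asian",
    "southeast_east_asian",
)

_ONSETS = ["b", "d", "f", "g", "h", "l", "m", "n", "p", "r", "s", "t", "br", "st", "gr", "pl"]
_VOWELS = ["a", "e", "i", "o", "u", "ai", "oo", "ou"]
_CODAS = ["", "n", "r", "s", "t", "l", "m", "nd", "rt"]

# Accented variants used to inject non-ASCII characters; NFKD maps each
# back to its base letter, so normalisation recovers the ASCII name.
_ACCENTED = {"a": "á", "e": "é", "i": "í", "o": "ó", "u": "ú", "c": "ç", "n": "ñ", "s": "š"}

_POOL_SEED = 20211215  # fixed: word pools are part of the study conditions


def _make_words(n: int, rng: np.random.Generator, taken: set[str]) -> list[str]:
    """Generate ``n`` distinct pronounceable words of 2-3 syllables."""
    words: list[str] = []
    while len(words) < n:
        k = 2 if rng.random() < 0.6 else 3
        word = "".join(
            _ONSETS[rng.integers(len(_ONSETS))]
            + _VOWELS[rng.integers(len(_VOWELS))]
            + (_CODAS[rng.integers(len(_CODAS))] if s == k - 1 else "")
            for s in range(k)
        )
        if word not in taken:
            taken.add(word)
            words.append(word)
    return words


def _default_pools(
    n_classes: int, words_per_class: int, shared_size: int
) -> tuple[list[list[str]], list[str], list[str], list[str]]:
    """Class pools, shared pool, place names and class affixes, all
    disjoint, from the fixed pool seed."""
    rng = np.random.default_rng(_POOL_SEED)
    taken: set[str] = set()
    class_pools = [_make_words(words_per_class, rng, taken) for _ in range(n_classes)]
    shared = _make_words(shared_size, rng, taken)
    places = _make_words(24, rng, taken)
    # Affixes use letters absent from the syllable alphabet, so they never
    # occur by chance inside generated words.
    rare = "qxzjwvk"
    affixes: list[str] = []
    while len(affixes) < n_classes:
        a = "".join(rare[rng.integers(len(rare))] for _ in range(3))
        if a not in affixes:
            affixes.append(a)
    return class_pools, shared, places, affixes


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.  Defaults describe a realistic mid-noise corpus;
    the helper constructors below pin the canonical test conditions."""

    classes: tuple[str, ...] = DEFAULT_CLASSES
    vocab_per_class: tuple[tuple[str, ...], ...] = ()
    shared_vocab: tuple[str, ...] = ()
    signal_strength: float = 0.8
    n_per_class: int = 500
    chain_rate: float = 0.05
    duplicate_rate: float = 0.02
    label_noise: float = 0.05
    nonascii_rate: float = 0.01
    subword_signal: bool = False
    n_areas: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "signal_strength",
            "chain_rate",
            "duplicate_rate",
            "label_noise",
            "nonascii_rate",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.n_per_class < 1:
            raise ValueError(f"n_per_class must be >= 1, got {self.n_per_class}")
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("classes must be unique")
        if self.vocab_per_class:
            if len(self.vocab_per_class) != len(self.classes):
                raise ValueError("vocab_per_class must have one pool per class")
            if any(len(pool) == 0 for pool in self.vocab_per_class):
                raise ValueError("vocab_per_class contains an empty pool")
        if self.shared_vocab is not None and self.vocab_per_class and not self.shared_vocab:
            if self.signal_strength < 1.0:
                raise ValueError("shared_vocab is empty but signal_strength < 1")


@dataclass
class SynthCorpus:
    """A generated corpus: records in emission order, the true class per
    record, and generator bookkeeping used as a test oracle."""

    records: list[OutletRecord]
    truth: list[str]
    population_table: Optional[dict[str, int]] = None
    base_names: tuple[str, ...] = ()
    config: Optional[SynthConfig] = None

    def __post_init__(self) -> None:
        if len(self.records) != len(self.truth):
            raise ValueError("one truth entry per record required")

    @property
    def n_base_records(self) -> int:
        """Number of distinct base businesses before chain/duplicate
        inflation — what deduplication should recover."""
        return len(self.base_names)

    def names(self) -> list[str]:
        return [r.name for r in self.records]


def default_config(**overrides) -> SynthConfig:
    """A 10-class corpus with the default word pools filled in."""
    classes = overrides.get("classes", DEFAULT_CLASSES)
    shared_size = overrides.pop("shared_size", 120)
    pools, shared, _, _ = _default_pools(len(classes), 8, shared_size)
    overrides.setdefault("vocab_per_class", tuple(tuple(p) for p in pools))
    overrides.setdefault("shared_vocab", tuple(shared))
    return SynthConfig(**overrides)


def separable_config(seed: int = 0, n_per_class: int = 500, **overrides) -> SynthConfig:
    """Fully separable corpus: disjoint class vocabularies, every word a
    signal word, no label noise."""
    overrides.setdefault("signal_strength", 1.0)
    overrides.setdefault("label_noise", 0.0)
    overrides.setdefault("nonascii_rate", 0.0)
    return default_config(seed=seed, n_per_class=n_per_class, **overrides)


def zero_signal_config(seed: int = 0, n_per_class: int = 500, **overrides) -> SynthConfig:
    """Names carry no class information: all words come from the shared
    pool, so any classifier is at chance."""
    overrides.setdefault("signal_strength", 0.0)
    overrides.setdefault("nonascii_rate", 0.0)
    return default_config(seed=seed, n_per_class=n_per_class, **overrides)


def subword_config(seed: int = 0, n_per_class: int = 500, **overrides) -> SynthConfig:
    """Subword-signal corpus: one word per name carries a class-specific
    3-character affix implanted at a random position.  The large shared
    vocabulary makes most affixed word *forms* in validation unseen during
    training, so whole-word scoring degrades while a character model can
    read the affix directly."""
    overrides.setdefault("subword_signal", True)
    overrides.setdefault("signal_strength", 0.9)
    overrides.setdefault("nonascii_rate", 0.0)
    overrides.setdefault("shared_size", 240)
    return default_config(seed=seed, n_per_class=n_per_class, **overrides)


def _make_name(
    cls_idx: int,
    config: SynthConfig,
    affixes: Sequence[str],
    rng: np.random.Generator,
) -> str:
    n_words = int(rng.integers(1, 6))
    class_pool = config.vocab_per_class[cls_idx]
    shared = config.shared_vocab or class_pool
    if config.subword_signal:
        words = [shared[rng.integers(len(shared))] for _ in range(n_words)]
        if rng.random() < config.signal_strength:
            w = int(rng.integers(n_words))
            word = words[w]
            pos = int(rng.integers(len(word) + 1))
            words[w] = word[:pos] + affixes[cls_idx] + word[pos:]
    else:
        words = [
            class_pool[rng.integers(len(class_pool))]
            if rng.random() < config.signal_strength
            else shared[rng.integers(len(shared))]
            for _ in range(n_words)
        ]
    return " ".join(words)


def _accent(name: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return name
    return "".join(
        _ACCENTED[c] if c in _ACCENTED and rng.random() < rate else c for c in name
    )


def generate_corpus(config: SynthConfig) -> SynthCorpus:
    """Generate a corpus under ``config``.

    Each class contributes exactly ``n_per_class`` base records with
    globally unique names.  A base record becomes a chain (2-5 suffixed
    replicas, replacing the base) with probability ``chain_rate``; each
    emitted record is exactly duplicated with probability
    ``duplicate_rate``.  Owner label 1 equals the true class except with
    probability ``label_noise``; a second random label and a third "halal"
    label appear at fixed realistic rates.  Reproducible for a fixed seed.
    """
    if not config.vocab_per_class:
        raise ValueError("vocab_per_class is empty; use default_config() to fill pools")
    rng = np.random.default_rng(config.seed)
    # separate stream so the accent rate never perturbs corpus structure
    accent_rng = np.random.default_rng([config.seed, 1])
    _, _, places, affixes = _default_pools(
        len(config.classes), 8, max(len(config.shared_vocab), 1)
    )

    classes = config.classes
    base_names: list[str] = []
    seen: set[str] = set()
    emitted: list[tuple[OutletRecord, str]] = []
    rid = 0

    # interleave classes during generation: global name uniqueness makes
    # late-drawn names systematically different (retries, salting), and a
    # class-blocked order would turn that into spurious class signal
    schedule = np.repeat(np.arange(len(classes)), config.n_per_class)
    rng.shuffle(schedule)
    for ci in schedule:
        cls = classes[ci]
        name = _make_name(ci, config, affixes, rng)
        attempts = 0
        while name in seen:
            name = _make_name(ci, config, affixes, rng)
            attempts += 1
            if attempts > 200:  # salt with a unique tag as a last resort
                name = f"{name} {len(seen)}"
        seen.add(name)
        base_names.append(name)

        label1 = (cls if rng.random() >= config.label_noise
                  else classes[rng.integers(len(classes))])

        variants: list[str]
        if rng.random() < config.chain_rate:
            n_branches = int(rng.integers(2, 6))
            branch_places = rng.choice(len(places), size=n_branches, replace=False)
            variants = [
                f"{name} - {places[p]}" if rng.random() < 0.5 else f"{name} ({places[p]})"
                for p in branch_places
            ]
        else:
            variants = [name]

        for variant in variants:
            # branches of a chain list their secondary labels
            # independently, as real branch listings do
            labels = [label1]
            if rng.random() < 0.4:
                labels.append(classes[rng.integers(len(classes))])
                if rng.random() < 0.2:
                    labels.append("halal")
            raw = _accent(variant, config.nonascii_rate, accent_rng)
            rec = OutletRecord(
                name=raw, labels=tuple(labels), record_id=f"r{rid:06d}"
            )
            rid += 1
            emitted.append((rec, cls))
            if rng.random() < config.duplicate_rate:
                dup = OutletRecord(
                    name=raw, labels=tuple(labels), record_id=f"r{rid:06d}"
                )
                rid += 1
                emitted.append((dup, cls))

    order = rng.permutation(len(emitted))
    records = [emitted[i][0] for i in order]
    truth = [emitted[i][1] for i in order]

    population_table = None
    if config.n_areas > 0:
        codes = [f"A{j:03d}" for j in range(config.n_areas)]
        population_table = {
            c: int(rng.integers(30_000, 300_000)) for c in codes
        }
        records = [
            OutletRecord(
                name=r.name,
                labels=r.labels,
                area_code=codes[rng.integers(config.n_areas)],
                record_id=r.record_id,
            )
            for r in records
        ]

    return SynthCorpus(
        records=records,
        truth=truth,
        population_table=population_table,
        base_names=tuple(base_names),
        config=config,
    )


def write_corpus_csv(corpus: SynthCorpus, path) -> None:
    """Write the standard outlet CSV: name,label1,label2,label3[,area_code]."""
    rows = []
    for rec in corpus.records:
        labels = list(rec.labels) + [""] * (3 - len(rec.labels))
        row = {"name": rec.name, "label1": labels[0], "label2": labels[1], "label3": labels[2]}
        if rec.area_code is not None:
            row["area_code"] = rec.area_code
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_truth_csv(corpus: SynthCorpus, path) -> None:
    pd.DataFrame(
        {
            "record_id": [r.record_id for r in corpus.records],
            "name": [r.name for r in corpus.records],
            "truth": corpus.truth,
        }
    ).to_csv(path, index=False)


def write_population_csv(corpus: SynthCorpus, path) -> None:
    if corpus.population_table is None:
        raise ValueError("corpus has no population table")
    pd.DataFrame(
        sorted(corpus.population_table.items()), columns=["area_code", "population"]
    ).to_csv(path, index=False)
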