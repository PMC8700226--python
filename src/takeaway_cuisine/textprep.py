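"""Business-name normalisation and character tokenization.

Outlet names arrive as free-form unicode ("Café Olé ", "©Wok").  The
pipeline works on a canonical form: lower-case printable ASCII with single
spaces.  Accented latin characters are transliterated to their ASCII base
character; symbols with no ASCII equivalent are dropped.

The classifier operates on characters, not words, so this module also
provides the character vocabulary (with reserved padding / unknown /
begin / end tokens) and an exact, invertible tokenizer.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "CleanName",
    "CharVocabulary",
    "EmptyNameError",
    "normalize_name",
    "build_vocabulary",
    "tokenize_chars",
    "detokenize_chars",
]

# Reserved tokens, in their fixed index order.
PAD = "<pad>"
UNK = "<unk>"
BOS = "<bos>"
EOS = "<eos>"
RESERVED = (PAD, UNK, BOS, EOS)

# A name may consist entirely of unconvertible symbols; downstream stages
# exclude such records rather than silently passing empty strings around.
CleanName = str


class EmptyNameError(ValueError):
    """Raised when a name normalises to the empty string."""


def normalize_name(raw: str, *, allow_empty: bool = True) -> CleanName:
    """Normalise a raw business name to lower-case ASCII.

    Accented characters are transliterated via NFKD decomposition (``é`` →
    ``e``); characters with no ASCII equivalent (``©``) are removed.
    Whitespace is trimmed and internal runs collapse to single spaces.

    Parameters
    ----------
    raw : str
        Any unicode string.
    allow_empty : bool
        When False, a name that normalises to "" raises
        :class:`EmptyNameError` instead of returning "".

    Idempotent: ``normalize_name(normalize_name(x)) == normalize_name(x)``.
    """
    # En/em dashes become hyphens so chain-suffix detection sees one form.
    text = raw.replace("–", "-").replace("—", "-")
    decomposed = unicodedata.normalize("NFKD", text)
    ascii_text = decomposed.encode("ascii", errors="ignore").decode("ascii")
    # Strip non-printable leftovers, lower-case, collapse whitespace.
    printable = "".join(c for c in ascii_text if c.isprintable() or c.isspace())
    cleaned = " ".join(printable.lower().split())
    if not cleaned and not allow_empty:
        raise EmptyNameError(f"name {raw!r} is empty after normalisation")
    return cleaned


@dataclass(frozen=True)
class CharVocabulary:
    """Character vocabulary: reserved tokens first, then characters in
    codepoint order.  ``index`` is a bijection token <-> integer."""

    tokens: tuple[str, ...]
    index: dict[str, int] = field(compare=False)

    @property
    def size(self) -> int:
        return len(self.tokens)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.tokens)

    def encode_char(self, char: str) -> int:
        return self.index.get(char, self.index[UNK])

    @property
    def pad_id(self) -> int:
        return self.index[PAD]

    @property
    def unk_id(self) -> int:
        return self.index[UNK]

    @property
    def bos_id(self) -> int:
        return self.index[BOS]

    @property
    def eos_id(self) -> int:
        return self.index[EOS]


def build_vocabulary(names: Iterable[CleanName]) -> CharVocabulary:
    """Build the character vocabulary covering every character in ``names``.

    Deterministic: reserved tokens occupy indices 0..3, then characters
    sorted by codepoint.  Raises ``ValueError`` on an empty collection.
    """
    chars: set[str] = set()
    n = 0
    for name in names:
        n += 1
        chars.update(name)
    if n == 0:
        raise ValueError("cannot build a vocabulary from an empty collection")
    tokens = RESERVED + tuple(sorted(chars))
    return CharVocabulary(tokens=tokens, index={t: i for i, t in enumerate(tokens)})


def tokenize_chars(name: CleanName, vocab: CharVocabulary) -> list[int]:
    """Encode ``name`` as ``[<bos>, c_1, ..., c_n, <eos>]`` token indices.

    Spaces are ordinary tokens; characters outside the vocabulary map to
    the unknown token.  ``detokenize_chars`` inverts this exactly for
    in-vocabulary names.
    """
    return [vocab.bos_id, *(vocab.encode_char(c) for c in name), vocab.eos_id]


def detokenize_chars(ids: Sequence[int], vocab: CharVocabulary) -> str:
    """Decode a token-index sequence back to its string, skipping the
    reserved tokens."""
    reserved = {vocab.pad_id, vocab.bos_id, vocab.eos_id}
    return "".join(vocab.tokens[i] for i in ids if i not in reserved)
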