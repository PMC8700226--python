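"""Rule-based assignment of a single cuisine class per outlet.

Each outlet gets exactly one class from a 10-point cuisine scheme
(chicken, kebab, pizza, burger, multi fast food, desserts,
sandwich/cafe/bakery, fish and chips, South Asian, Southeast & East
Asian) by a fixed priority cascade:

1. **chain** — the outlet's base name is a known retail chain; its class
   is assigned directly (e.g. "kfc" -> chicken) for consistency across
   branches and franchises.
2. **multi_keyword** — two or more of the fast-food keywords (chicken,
   kebab, pizza, burger) appear as whole words in the name -> multi fast
   food.
3. **single_keyword** — exactly one keyword appears -> that class.
4. **owner_label** — the first owner-assigned label that maps to a class.

Anything else is UNCLASSIFIED.  Owner labels map through a configurable
table; labels of cuisines with too few outlets to learn are EXCLUDED and
the "halal" descriptor (always a third label) is IGNORED, meaning later
labels are still consulted.

A six-point variant collapses chicken/kebab/pizza/burger and multi fast
food into a single multi-fast-food class via ``collapse_map``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import yaml

from .records import UNCLASSIFIED, LabeledOutlet, OutletRecord
from .textprep import normalize_name

__all__ = [
    "EXCLUDED",
    "IGNORED",
    "CuisineScheme",
    "default_scheme",
    "six_point_collapse_map",
    "map_owner_label",
    "detect_name_keywords",
    "assign_cuisine",
    "assign_all",
    "collapse_scheme",
    "load_scheme",
]

logger = logging.getLogger(__name__)

#: Owner-label fates that do not assign a class.
EXCLUDED = "<excluded>"
IGNORED = "<ignored>"

TEN_POINT_CLASSES = (
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

DEFAULT_NAME_KEYWORDS = {
    "chicken": "chicken",
    "kebab": "kebab",
    "pizza": "pizza",
    "burger": "burger",
}

# Major chains (>50 UK stores) whose class is assigned a priori.
DEFAULT_CHAIN_MAP = {
    "mcdonald's": "burger",
    "burger king": "burger",
    "kfc": "chicken",
    "pizza hut": "pizza",
    "papa john's": "pizza",
    "domino's": "pizza",
    "subway": "sandwich_cafe_bakery",
    "greggs": "sandwich_cafe_bakery",
}

# Owner labels -> class.  The platform's full label list is much larger;
# this default covers the class names themselves plus common labels, and is
# meant to be extended via a scheme config file for real data.
DEFAULT_OWNER_LABEL_MAP = {
    "chicken": "chicken",
    "kebab": "kebab",
    "kebabs": "kebab",
    "pizza": "pizza",
    "burger": "burger",
    "burgers": "burger",
    "multi fast food": "multi_fast_food",
    "multi_fast_food": "multi_fast_food",
    "desserts": "desserts",
    "dessert": "desserts",
    "sandwich_cafe_bakery": "sandwich_cafe_bakery",
    "sandwiches": "sandwich_cafe_bakery",
    "cafe": "sandwich_cafe_bakery",
    "bakery": "sandwich_cafe_bakery",
    "fish_and_chips": "fish_and_chips",
    "fish and chips": "fish_and_chips",
    "fish & chips": "fish_and_chips",
    "south_asian": "south_asian",
    "south asian": "south_asian",
    "indian": "south_asian",
    "southeast_east_asian": "southeast_east_asian",
    "southeast & east asian": "southeast_east_asian",
    "southeast and east asian": "southeast_east_asian",
    "chinese": "southeast_east_asian",
    "thai": "southeast_east_asian",
    "japanese": "southeast_east_asian",
    # Labels never used to define cuisine type:
    "halal": IGNORED,
    # Cuisines with too few outlets to train on:
    "russian": EXCLUDED,
    "tapas": EXCLUDED,
    "mexican": EXCLUDED,
    "healthy": EXCLUDED,
}


@dataclass(frozen=True)
class CuisineScheme:
    """A cuisine classification system: class set, owner-label mapping,
    name keywords, chain overrides and an optional collapse onto a reduced
    class set."""

    classes: tuple[str, ...] = TEN_POINT_CLASSES
    owner_label_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_OWNER_LABEL_MAP)
    )
    name_keywords: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_NAME_KEYWORDS)
    )
    chain_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CHAIN_MAP))
    collapse_map: Optional[dict[str, str]] = None
    keyword_whole_word: bool = True
    multi_keyword_class: str = "multi_fast_food"

    def __post_init__(self) -> None:
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("scheme classes must be unique")
        for table, name in ((self.chain_map, "chain_map"), (self.name_keywords, "name_keywords")):
            bad = set(table.values()) - set(self.classes)
            if bad:
                raise ValueError(f"{name} targets {sorted(bad)} are not scheme classes")
        if self.collapse_map is not None:
            missing = set(self.classes) - set(self.collapse_map)
            if missing:
                raise ValueError(f"collapse_map is missing classes {sorted(missing)}")


def six_point_collapse_map(classes: Sequence[str] = TEN_POINT_CLASSES) -> dict[str, str]:
    """Collapse map for the six-point variant: the four fast-food classes
    and multi_fast_food merge into multi_fast_food; the rest are fixed."""
    merged = {"chicken", "kebab", "pizza", "burger", "multi_fast_food"}
    return {c: ("multi_fast_food" if c in merged else c) for c in classes}


def default_scheme(*, six_point: bool = False) -> CuisineScheme:
    """The default 10-point scheme; with ``six_point=True`` the collapse
    map is attached."""
    return CuisineScheme(collapse_map=six_point_collapse_map() if six_point else None)


def map_owner_label(label: str, scheme: CuisineScheme) -> str:
    """Map a normalised owner label to a class, EXCLUDED or IGNORED.

    Unknown labels are EXCLUDED with a logged warning: a label absent from
    the mapping cannot contribute a class.
    """
    key = normalize_name(label)
    if key in scheme.owner_label_map:
        return scheme.owner_label_map[key]
    logger.warning("owner label %r not in scheme mapping; excluded", label)
    return EXCLUDED


def detect_name_keywords(name: str, scheme: CuisineScheme) -> set[str]:
    """Classes whose keyword occurs in the (normalised) name.

    Whole-word by default, so "kebabish" does not match "kebab"; set
    ``keyword_whole_word=False`` on the scheme for substring matching.
    """
    norm = normalize_name(name)
    hits = set()
    for keyword, cls in scheme.name_keywords.items():
        if scheme.keyword_whole_word:
            if re.search(rf"\b{re.escape(keyword)}\b", norm):
                hits.add(cls)
        elif keyword in norm:
            hits.add(cls)
    return hits


def assign_cuisine(record: OutletRecord, scheme: CuisineScheme) -> LabeledOutlet:
    """Assign one cuisine class to ``record`` by the priority cascade
    chain > name keywords > first mappable owner label."""
    norm = normalize_name(record.name)
    if norm in scheme.chain_map:
        return LabeledOutlet(record, scheme.chain_map[norm], "chain")

    keyword_classes = detect_name_keywords(norm, scheme)
    if len(keyword_classes) >= 2:
        return LabeledOutlet(record, scheme.multi_keyword_class, "multi_keyword")
    if len(keyword_classes) == 1:
        return LabeledOutlet(record, next(iter(keyword_classes)), "single_keyword")

    for label in record.labels:
        mapped = map_owner_label(label, scheme)
        if mapped == IGNORED or mapped == EXCLUDED:
            continue
        return LabeledOutlet(record, mapped, "owner_label")
    return LabeledOutlet(record)


def assign_all(
    records: Iterable[OutletRecord], scheme: CuisineScheme
) -> list[LabeledOutlet]:
    return [assign_cuisine(r, scheme) for r in records]


def collapse_scheme(labeled: LabeledOutlet, scheme: CuisineScheme) -> LabeledOutlet:
    """Map an assigned class onto the reduced class set; UNCLASSIFIED is
    unchanged.  Requires ``scheme.collapse_map``."""
    if scheme.collapse_map is None:
        raise ValueError("scheme has no collapse_map")
    if labeled.cuisine == UNCLASSIFIED:
        return labeled
    return replace(labeled, cuisine=scheme.collapse_map[labeled.cuisine])


def load_scheme(path) -> CuisineScheme:
    """Load a scheme from a YAML file.

    Recognised keys: ``classes``, ``owner_label_map``, ``name_keywords``,
    ``chain_map``, ``collapse_map``, ``keyword_whole_word``,
    ``multi_keyword_class``.  Omitted keys fall back to the defaults.
    In ``owner_label_map`` the special values ``excluded`` and ``ignored``
    mark non-classifying labels.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    if "classes" in raw:
        kwargs["classes"] = tuple(raw["classes"])
    special = {"excluded": EXCLUDED, "ignored": IGNORED}
    if "owner_label_map" in raw:
        kwargs["owner_label_map"] = {
            normalize_name(k): special.get(str(v).lower(), v)
            for k, v in raw["owner_label_map"].items()
        }
    for key in ("name_keywords", "chain_map", "collapse_map"):
        if key in raw:
            kwargs[key] = dict(raw[key])
    for key in ("keyword_whole_word", "multi_keyword_class"):
        if key in raw:
            kwargs[key] = raw[key]
    return CuisineScheme(**kwargs)
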