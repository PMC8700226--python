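"""Chain detection, location-suffix stripping and record deduplication.

Online ordering platforms list every branch of a chain separately, usually
as the chain name followed by a location: ``"roosters piri piri - stockwell"``
or ``"tops pizza (trumpington)"``.  Identical independent names ("golden
wok") also repeat.  Keeping duplicates would leak training names into
validation, so duplicate groups are collapsed to a single record per base
name.  Owner labels are not always consistent across branches; the two most
frequent labels across the group are retained, ties broken alphabetically.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .records import OutletRecord
from .textprep import normalize_name

__all__ = [
    "DuplicateGroup",
    "strip_location_suffix",
    "group_duplicates",
    "reconcile_labels",
    "deduplicate",
    "load_chain_list",
]

# One trailing " - <text>" segment or one trailing "(<text>)" group.  Only a
# single suffix is stripped so names like "fish (and) chips (leyton)" lose
# only the final group.
_HYPHEN_SUFFIX = re.compile(r"\s+[-–]\s+[^-()]*$")
_BRACKET_SUFFIX = re.compile(r"\s*\(([^()]*)\)\s*$")


def strip_location_suffix(name: str) -> str:
    """Remove a single trailing location suffix from ``name``.

    Handles both observed branch-name patterns: a hyphen- (or en-dash-)
    separated trailing segment and a trailing parenthesised group.  Names
    without a suffix are returned unchanged (trimmed).
    """
    stripped = _BRACKET_SUFFIX.sub("", name)
    if stripped == name:
        stripped = _HYPHEN_SUFFIX.sub("", name)
    return stripped.strip()


@dataclass(frozen=True)
class DuplicateGroup:
    """Records sharing a base name after suffix stripping + normalisation."""

    base_name: str
    members: tuple[OutletRecord, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a duplicate group must have at least one member")


def _base_name(name: str, known_chains: frozenset[str]) -> str:
    norm = normalize_name(name)
    if norm in known_chains:
        return norm
    base = normalize_name(strip_location_suffix(norm))
    return base if base else norm


def group_duplicates(
    records: Sequence[OutletRecord],
    known_chains: Iterable[str] = (),
) -> list[DuplicateGroup]:
    """Partition ``records`` by base name.

    A priori known chains are grouped on their exact normalised name
    whether or not a suffix is present; all other records are grouped on
    their suffix-stripped, normalised name.  Singletons form singleton
    groups.  Group order follows first appearance in the input.
    """
    chains = frozenset(normalize_name(c) for c in known_chains)
    buckets: dict[str, list[OutletRecord]] = {}
    for rec in records:
        norm = normalize_name(rec.name)
        base = norm if norm in chains else _base_name(rec.name, chains)
        buckets.setdefault(base, []).append(rec)
    return [
        DuplicateGroup(base_name=base, members=tuple(members))
        for base, members in buckets.items()
    ]


def reconcile_labels(group: DuplicateGroup) -> tuple[str, ...]:
    """Return the <=2 most frequent owner labels across the group.

    Frequency ties are broken alphabetically; the result is ordered by
    frequency descending, then alphabetically.  A group whose members carry
    no labels yields an empty tuple.

    A singleton group keeps its member's own label order (first two): the
    owner's ordering is informative, and with every frequency equal to 1
    the tie rule would otherwise scramble it.
    """
    if len(group.members) == 1:
        labels = [normalize_name(l) for l in group.members[0].labels]
        return tuple(l for l in labels if l)[:2]
    counts = Counter(
        normalize_name(label)
        for member in group.members
        for label in member.labels
        if normalize_name(label)
    )
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return tuple(label for label, _ in ranked[:2])


def deduplicate(groups: Sequence[DuplicateGroup]) -> list[OutletRecord]:
    """Collapse each group to one record with the base name and reconciled
    labels.  Area code and record id are taken from the first member."""
    out = []
    for group in groups:
        first = group.members[0]
        out.append(
            OutletRecord(
                name=group.base_name,
                labels=reconcile_labels(group),
                area_code=first.area_code,
                record_id=first.record_id,
            )
        )
    return out


def load_chain_list(path) -> list[str]:
    """Read a known-chains file: one chain base name per line, '#' comments
    and blank lines ignored."""
    chains = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                chains.append(line)
    return chains
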