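"""Core record types shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = ["OutletRecord", "LabeledOutlet", "UNCLASSIFIED"]

#: Sentinel cuisine value for outlets no rule or label could classify.
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class OutletRecord:
    """One takeaway food outlet: a business name plus up to three
    owner-assigned cuisine labels and an optional area code."""

    name: str
    labels: tuple[str, ...] = ()
    area_code: Optional[str] = None
    record_id: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.labels) > 3:
            raise ValueError(
                f"record {self.record_id or self.name!r} has "
                f"{len(self.labels)} labels; at most 3 are allowed"
            )

    def with_name(self, name: str) -> "OutletRecord":
        return replace(self, name=name)

    def with_labels(self, labels: tuple[str, ...]) -> "OutletRecord":
        return replace(self, labels=labels)


@dataclass(frozen=True)
class LabeledOutlet:
    """An outlet with its single assigned cuisine class.

    ``provenance`` records which rule fired: ``chain``, ``multi_keyword``,
    ``single_keyword`` or ``owner_label``; it is ``None`` iff the outlet is
    unclassified.
    """

    record: OutletRecord
    cuisine: str = UNCLASSIFIED
    provenance: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.cuisine == UNCLASSIFIED) != (self.provenance is None):
            raise ValueError(
                "provenance must be present exactly when a cuisine is assigned"
            )

    @property
    def name(self) -> str:
        return self.record.name
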