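"""The SIMEDID item bank: four developmental subscales of milestone items.

The instrument screens early-childhood development (0-60 months) in four
domains -- gross motor, fine motor, language, and socioemotional -- with
33/33/34/33 binary pass/fail items per domain, arranged in ascending
difficulty. Item codes follow the field convention MG1..MG33, MF1..MF33,
DL1..DL34, DS1..DS33; indices are 1-based throughout the package so that
``index`` always matches the numeric part of the item code.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

DOMAINS: tuple[str, ...] = ("gross_motor", "fine_motor", "language", "socioemotional")

#: Subscale sizes of the packaged SIMEDID instrument.
SIMEDID_COUNTS: Mapping[str, int] = {
    "gross_motor": 33,
    "fine_motor": 33,
    "language": 34,
    "socioemotional": 33,
}


class ItemBankError(ValueError):
    """Base class for item-bank validation failures."""


class DuplicateItemIdError(ItemBankError):
    def __init__(self, item_id: str):
        self.item_id = item_id
        super().__init__(f"duplicate item_id {item_id!r} in item bank")


class NonContiguousIndexError(ItemBankError):
    def __init__(self, domain: str, indices: list[int]):
        self.domain = domain
        super().__init__(
            f"domain {domain!r}: indices must be contiguous 1..k, got {sorted(indices)}"
        )


class DomainCountError(ItemBankError):
    def __init__(self, domain: str, expected: int, actual: int):
        self.domain = domain
        super().__init__(
            f"domain {domain!r}: expected {expected} items, found {actual}"
        )


@dataclass(frozen=True)
class Item:
    """One milestone item: a binary pass/fail behavioural criterion."""

    item_id: str
    domain: str
    index: int  # 1-based position within the subscale (ascending difficulty)
    label: str


class ItemBank:
    """Ordered collection of items grouped by developmental domain.

    Items within each domain are stored sorted by their 1-based index and
    validated for uniqueness and contiguity on construction.
    """

    def __init__(self, items: list[Item]):
        self._by_domain: dict[str, list[Item]] = {}
        seen: set[str] = set()
        for it in items:
            if it.item_id in seen:
                raise DuplicateItemIdError(it.item_id)
            seen.add(it.item_id)
            self._by_domain.setdefault(it.domain, []).append(it)
        for domain, dom_items in self._by_domain.items():
            dom_items.sort(key=lambda it: it.index)
            indices = [it.index for it in dom_items]
            if indices != list(range(1, len(dom_items) + 1)):
                raise NonContiguousIndexError(domain, indices)

    @property
    def domains(self) -> tuple[str, ...]:
        # preserve canonical ordering for known domains, insertion order otherwise
        known = [d for d in DOMAINS if d in self._by_domain]
        extra = [d for d in self._by_domain if d not in DOMAINS]
        return tuple(known + extra)

    def items_for(self, domain: str) -> list[Item]:
        return list(self._by_domain[domain])

    def domain_size(self, domain: str) -> int:
        return len(self._by_domain[domain])

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_domain.values())

    def __iter__(self) -> Iterator[Item]:
        for domain in self.domains:
            yield from self._by_domain[domain]

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self]

    def check_counts(self, expected: Mapping[str, int]) -> None:
        """Raise :class:`DomainCountError` if any domain size disagrees."""
        for domain, count in expected.items():
            actual = len(self._by_domain.get(domain, []))
            if actual != count:
                raise DomainCountError(domain, count, actual)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(it.item_id, it.domain, it.index, it.label) for it in self],
            columns=["item_id", "domain", "index", "label"],
        )


def load_item_bank(
    path: str | Path, expected_counts: Mapping[str, int] | None = None
) -> ItemBank:
    """Load and validate an item bank from a CSV table.

    The file must have a header ``item_id,domain,index,label`` and one row per
    item. Validation raises a distinct error for duplicate ids, non-contiguous
    indices, and (when ``expected_counts`` is given) domain-count mismatches.
    """
    df = pd.read_csv(path, dtype={"item_id": str, "domain": str, "label": str})
    required = {"item_id", "domain", "index", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ItemBankError(f"item file missing columns: {sorted(missing)}")
    items = [
        Item(r.item_id, r.domain, int(r.index), r.label)
        for r in df.itertuples(index=False)
    ]
    bank = ItemBank(items)
    if expected_counts is not None:
        bank.check_counts(expected_counts)
    return bank


def write_bank(bank: ItemBank, path: str | Path) -> None:
    """Write a bank back to the CSV layout accepted by :func:`load_item_bank`."""
    bank.to_frame().to_csv(path, index=False)


def default_bank() -> ItemBank:
    """The packaged 133-item SIMEDID bank (English labels), 33/33/34/33."""
    ref = resources.files("milenorm.data").joinpath("simedid_items.csv")
    with resources.as_file(ref) as path:
        return load_item_bank(path, expected_counts=SIMEDID_COUNTS)
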