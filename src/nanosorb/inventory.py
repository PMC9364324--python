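"""Curated inventory of enteric microbial metabolites.

The inventory is a literature-derived table of metabolites produced,
modified or regulated by gut microbiota, each assigned to one of thirteen
functional/structural categories (or the catch-all ``other``) and tagged
with the indices of the source reviews (1..10, in inclusion order) that
report it.  Two analyses operate on it: cumulative discovery counts as
reviews are added (a literature-saturation curve) and per-category counts.

A metabolite may belong to more than one category (e.g. acetylcholine is
both a tryptophan metabolite and a neurotransmitter); such records are
stored once with a multi-valued category field, and category counts expand
them, so counts sum to at least the number of unique records.

The packaged inventory (``data/inventory.csv``) is a reconstruction:
names and categories follow the published overview where listed, while the
remaining members and the per-review provenance are deterministic fillers
encoding the published cumulative totals.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "CATEGORIES",
    "MetaboliteRecord",
    "InventoryTable",
    "load_inventory",
    "load_packaged_inventory",
    "cumulative_discovery",
    "category_counts",
]

#: Closed category vocabulary (thirteen categories plus the catch-all).
CATEGORIES = frozenset(
    {
        "MAMPs", "vitamins", "SCFAs", "PBAs", "SBAs", "CBAs", "tryptophan",
        "polyamines", "choline", "neurotransmitters", "lipid", "phenolic",
        "proteins/enzymes", "other",
    }
)


@dataclass(frozen=True)
class MetaboliteRecord:
    """One metabolite: name, one or more categories, optional SMILES, and
    the set of source-review indices that report it."""

    name: str
    categories: tuple[str, ...]
    smiles: str = ""
    source_reviews: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        bad = [c for c in self.categories if c not in CATEGORIES]
        if bad:
            raise ValueError(f"record {self.name!r}: unknown categories {bad}")
        if not self.categories:
            raise ValueError(f"record {self.name!r}: needs at least one category")
        if not self.source_reviews:
            raise ValueError(f"record {self.name!r}: source_reviews is empty")


@dataclass(frozen=True)
class InventoryTable:
    records: tuple[MetaboliteRecord, ...]

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate metabolite names: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _parse_rows(rows: Iterable[dict], source: str) -> InventoryTable:
    records = []
    for i, row in enumerate(rows, start=1):
        missing = {"name", "category", "smiles", "source_reviews"} - set(row)
        if missing:
            raise ValueError(f"{source}: missing columns {sorted(missing)}")
        cats = tuple(c.strip() for c in row["category"].split("|") if c.strip())
        try:
            reviews = frozenset(
                int(tok) for tok in row["source_reviews"].split(";") if tok.strip()
            )
        except ValueError as err:
            raise ValueError(
                f"{source} row {i} ({row['name']!r}): bad source_reviews"
            ) from err
        try:
            records.append(
                MetaboliteRecord(
                    name=row["name"].strip(),
                    categories=cats,
                    smiles=(row["smiles"] or "").strip(),
                    source_reviews=reviews,
                )
            )
        except ValueError as err:
            raise ValueError(f"{source} row {i}: {err}") from err
    return InventoryTable(tuple(records))


def load_inventory(path: str | Path | io.TextIOBase) -> InventoryTable:
    """Load an inventory CSV (columns name, category, smiles,
    source_reviews; '#'-prefixed lines are comments; multi-category records
    separate labels with '|', review indices with ';')."""
    text = path.read() if hasattr(path, "read") else Path(path).read_text()
    lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
    reader = csv.DictReader(lines)
    source = getattr(path, "name", str(path))
    return _parse_rows(reader, source)


def load_packaged_inventory() -> InventoryTable:
    """The packaged 170-metabolite reconstruction."""
    text = resources.files("nanosorb").joinpath("data/inventory.csv").read_text()
    return load_inventory(io.StringIO(text))


def cumulative_discovery(
    inv: InventoryTable, review_order: Sequence[int]
) -> list[int]:
    """Cumulative unique-metabolite counts as reviews are added.

    The k-th value counts metabolites whose earliest source review (in
    ``review_order``) is among the first k reviews; the final value is the
    total inventory size.
    """
    order = list(review_order)
    position = {rev: i for i, rev in enumerate(order)}
    known = {rev for r in inv for rev in r.source_reviews}
    unknown = known - set(order)
    if unknown:
        raise ValueError(f"source reviews not in review_order: {sorted(unknown)}")
    counts = [0] * len(order)
    for rec in inv:
        first = min(position[rev] for rev in rec.source_reviews)
        counts[first] += 1
    out, total = [], 0
    for c in counts:
        total += c
        out.append(total)
    return out


def category_counts(inv: InventoryTable) -> dict[str, int]:
    """Number of metabolites per category; multi-category records are
    counted once in each of their categories."""
    counts = {c: 0 for c in sorted(CATEGORIES)}
    for rec in inv:
        for c in rec.categories:
            counts[c] += 1
    return counts
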