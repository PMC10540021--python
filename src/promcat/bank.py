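"""Item banks for polytomous IRT-scored questionnaires.

An item bank holds the graded-response-model parameters of every item in a
patient-reported outcome measure (PROM): one discrimination (slope) ``a`` and
``K - 1`` ordered category thresholds ``b_1 < ... < b_{K-1}`` per item, all on
a common latent z-score scale where, by convention, higher scores mean greater
symptom severity.

Banks are interchanged as plain CSV with header
``item_id,content,n_categories,a,b1,b2,...``; items with fewer categories
leave trailing threshold columns empty.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "ItemParameters",
    "ItemBank",
    "BankValidationError",
    "validate_bank",
    "read_bank_csv",
    "write_bank_csv",
    "make_synthetic_bank",
]


class BankValidationError(ValueError):
    """Raised when an item bank fails validation on read."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("invalid item bank:\n" + "\n".join(f"  - {p}" for p in problems))


@dataclass(frozen=True)
class ItemParameters:
    """Graded-response-model parameters for one ordinal item.

    Categories are numbered 1..K externally; thresholds are numbered 1..K-1,
    with threshold ``b_k`` separating categories <= k from categories > k.
    A valid item has ``a > 0`` and strictly increasing thresholds; violations
    are reported by :func:`validate_bank` rather than raised at construction
    so that malformed CSV rows can be collected into one report.
    """

    item_id: str
    a: float
    thresholds: tuple[float, ...]
    content: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "thresholds", tuple(float(b) for b in self.thresholds))
        object.__setattr__(self, "a", float(self.a))

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1

    def problems(self) -> list[str]:
        """Invariant violations for this item, empty if valid."""
        out: list[str] = []
        if not self.a > 0:
            out.append(f"item {self.item_id!r}: discrimination a={self.a} is not positive")
        b = np.asarray(self.thresholds)
        if b.size == 0:
            out.append(f"item {self.item_id!r}: no thresholds (needs K >= 2 categories)")
        elif b.size > 1 and not np.all(np.diff(b) > 0):
            out.append(f"item {self.item_id!r}: thresholds not strictly increasing: {self.thresholds}")
        return out


@dataclass(frozen=True)
class ItemBank:
    """Ordered collection of items sharing one latent scale.

    ``higher_is_worse`` records the scale orientation (True: a higher latent
    score indicates greater symptom severity).
    """

    items: tuple[ItemParameters, ...]
    higher_is_worse: bool = True
    _index: dict = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        object.__setattr__(self, "_index", {it.item_id: i for i, it in enumerate(self.items)})

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[ItemParameters]:
        return iter(self.items)

    def __getitem__(self, key: int | str) -> ItemParameters:
        if isinstance(key, str):
            return self.items[self._index[key]]
        return self.items[key]

    def index_of(self, item_id: str) -> int:
        return self._index[item_id]

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)


def validate_bank(bank: ItemBank) -> list[str]:
    """Return every invariant violation in the bank; empty iff valid."""
    problems: list[str] = []
    seen: set[str] = set()
    for it in bank.items:
        if it.item_id in seen:
            problems.append(f"duplicate item_id {it.item_id!r}")
        seen.add(it.item_id)
        problems.extend(it.problems())
    return problems


_HEADER_FIXED = ["item_id", "content", "n_categories", "a"]


def _parse_bank_rows(reader: csv.reader, source: str) -> ItemBank:
    header = next(reader, None)
    if header is None or [h.strip() for h in header[:4]] != _HEADER_FIXED:
        raise BankValidationError(
            [f"{source}: expected header starting 'item_id,content,n_categories,a', got {header}"]
        )
    items: list[ItemParameters] = []
    problems: list[str] = []
    for lineno, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        try:
            item_id, content, n_cat_s, a_s = row[0], row[1], row[2], row[3]
            n_cat = int(n_cat_s)
            bs = [float(c) for c in row[4 : 4 + n_cat - 1] if c.strip() != ""]
            if len(bs) != n_cat - 1:
                problems.append(
                    f"{source} line {lineno}: item {item_id!r} declares {n_cat} categories "
                    f"but has {len(bs)} thresholds"
                )
                continue
            trailing = [c for c in row[4 + n_cat - 1 :] if c.strip() != ""]
            if trailing:
                problems.append(
                    f"{source} line {lineno}: item {item_id!r} has non-empty trailing "
                    f"threshold columns {trailing}"
                )
            items.append(ItemParameters(item_id=item_id, a=float(a_s), thresholds=tuple(bs), content=content))
        except (ValueError, IndexError) as exc:
            problems.append(f"{source} line {lineno}: unparseable row ({exc})")
    bank = ItemBank(items=tuple(items))
    problems.extend(validate_bank(bank))
    if problems:
        raise BankValidationError(problems)
    return bank


def read_bank_csv(path: str | Path) -> ItemBank:
    """Read an item bank, rejecting it with a full report if invalid."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        return _parse_bank_rows(csv.reader(fh), source=str(path))


def read_bank_csv_string(text: str, source: str = "<string>") -> ItemBank:
    return _parse_bank_rows(csv.reader(_io.StringIO(text)), source=source)


def write_bank_csv(bank: ItemBank, path: str | Path) -> None:
    """Write a bank in the interchange CSV layout (UTF-8, comma, header)."""
    max_b = max((it.n_categories - 1 for it in bank.items), default=0)
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_HEADER_FIXED + [f"b{i}" for i in range(1, max_b + 1)])
        for it in bank.items:
            bs = [repr(b) for b in it.thresholds]
            bs += [""] * (max_b - len(bs))
            w.writerow([it.item_id, it.content, it.n_categories, repr(it.a)] + bs)


def make_synthetic_bank(
    n_items: int = 11,
    n_categories: int = 7,
    seed: int = 20220713,
    discrimination_range: tuple[float, float] = (1.5, 2.5),
    midpoint_range: tuple[float, float] = (-2.0, 2.0),
    threshold_spacing: float = 0.7,
) -> ItemBank:
    """Generate a synthetic item bank emulating an 11-item, 7-category hand
    function PROM.

    The real instrument's registry-derived calibration is not publicly
    printed, so this stand-in reproduces only its *structure*: item
    discriminations drawn uniformly from ``discrimination_range`` and, per
    item, equally spaced thresholds (spacing ``threshold_spacing``) centred on
    midpoints spread evenly over ``midpoint_range``. The default seed is fixed
    so the shipped bank is reproducible.
    """
    rng = np.random.default_rng(seed)
    a = rng.uniform(*discrimination_range, size=n_items)
    if n_items > 1:
        midpoints = np.linspace(midpoint_range[0], midpoint_range[1], n_items)
    else:
        midpoints = np.array([0.5 * (midpoint_range[0] + midpoint_range[1])])
    # interleave so neighbouring bank positions do not target neighbouring
    # severity levels (mimics real questionnaires, where item order is
    # thematic, not difficulty-ordered)
    order = rng.permutation(n_items)
    offsets = (np.arange(n_categories - 1) - (n_categories - 2) / 2.0) * threshold_spacing
    items = []
    for i in range(n_items):
        items.append(
            ItemParameters(
                item_id=f"item{i + 1:02d}",
                a=float(a[i]),
                thresholds=tuple(midpoints[order[i]] + offsets),
                content=f"synthetic hand-function item {i + 1}",
            )
        )
    return ItemBank(items=tuple(items))
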