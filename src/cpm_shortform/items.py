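"""Item bank for Raven's Coloured Progressive Matrices (CPM).

The CPM comprises 36 items in three 12-item sets (A, Ab, B), each set ordered
by ascending difficulty. Items A1 and A2 are practice items administered with
feedback and are excluded from scoring, so the maximum total score is 34.

This module holds the published per-item proportions correct, the manual's
cognitive-demand classification, the published 12-item short form, and the
per-length development table (best candidate per short-form length with its
test-set correlation and percent gain). These constants are the calibration
targets for the synthetic-cohort generator and the fixtures for desk checks
of the stopping rule and content-validity bookkeeping.
"""

from __future__ import annotations

import pandas as pd

SET_LABELS = ("A", "Ab", "B")

ITEM_IDS: tuple[str, ...] = tuple(
    f"{s}{i}" for s in SET_LABELS for i in range(1, 13)
)

PRACTICE_ITEMS: tuple[str, str] = ("A1", "A2")

#: The 34 items that contribute to the total score.
SCORED_ITEMS: tuple[str, ...] = tuple(
    i for i in ITEM_IDS if i not in PRACTICE_ITEMS
)

#: Published proportion of correct answers per item (whole sample, n = 336).
ITEM_PROPORTIONS: dict[str, float] = {
    "A1": 0.98, "A2": 0.99, "A3": 0.99, "A4": 0.98, "A5": 0.89, "A6": 0.87,
    "A7": 0.55, "A8": 0.62, "A9": 0.58, "A10": 0.61, "A11": 0.13, "A12": 0.10,
    "Ab1": 0.90, "Ab2": 0.87, "Ab3": 0.84, "Ab4": 0.69, "Ab5": 0.77,
    "Ab6": 0.68, "Ab7": 0.63, "Ab8": 0.36, "Ab9": 0.47, "Ab10": 0.38,
    "Ab11": 0.51, "Ab12": 0.27,
    "B1": 0.98, "B2": 0.70, "B3": 0.74, "B4": 0.80, "B5": 0.59, "B6": 0.50,
    "B7": 0.39, "B8": 0.14, "B9": 0.15, "B10": 0.22, "B11": 0.15, "B12": 0.09,
}

#: The published 12-item short form, in canonical A -> Ab -> B order.
FINAL_SHORT_FORM: tuple[str, ...] = (
    "A10", "Ab5", "Ab6", "Ab7", "Ab8", "Ab9",
    "B2", "B4", "B5", "B7", "B8", "B11",
)

#: Cognitive-demand domains from the CPM manual, keyed by the item ranges
#: they cover. Domain names recur across sets, so keys carry the set label.
DOMAIN_RANGES: dict[str, tuple[str, ...]] = {
    "A: completion of simple patterns": tuple(f"A{i}" for i in range(1, 9)),
    "A: progressive change in one direction": ("A9", "A10"),
    "A: progressive change in two directions": ("A11", "A12"),
    "Ab: completion of discrete identical patterns": ("Ab1", "Ab2", "Ab3"),
    "Ab: completion of discrete patterns as a related whole": tuple(
        f"Ab{i}" for i in range(4, 13)
    ),
    "B: completion of discrete identical patterns": ("B1", "B2"),
    "B: completion of discrete patterns as a related whole": ("B3", "B4", "B5"),
    "B: concrete or coherent reasoning by spatial analogy": (
        "B6", "B7", "B8", "B9"
    ),
    "B: discrete or abstract reasoning by logical analogy": (
        "B10", "B11", "B12"
    ),
}

#: item id -> domain, derived from the ranges above.
DOMAIN_MAP: dict[str, str] = {
    item: domain for domain, items in DOMAIN_RANGES.items() for item in items
}

#: Published development table: best candidate per length. Length 9 never
#: appeared in the search, so gains run between consecutive available
#: lengths. ``pct_change`` is the printed percent gain in test-set r over the
#: previous available length (None for the shortest form).
DEVELOPMENT_TABLE_ROWS: tuple[dict, ...] = (
    {"length": 2, "items": ("Ab6", "B5"), "mixing": 0.70, "penalty": 3.00,
     "r": 0.63, "pct_change": None},
    {"length": 3, "items": ("Ab6", "Ab7", "B5"), "mixing": 0.90,
     "penalty": 2.15, "r": 0.69, "pct_change": 8.34},
    {"length": 4, "items": ("Ab5", "Ab6", "Ab7", "B5"), "mixing": 0.65,
     "penalty": 2.95, "r": 0.75, "pct_change": 8.78},
    {"length": 5, "items": ("Ab5", "Ab6", "Ab7", "Ab9", "B5"),
     "mixing": 0.75, "penalty": 2.35, "r": 0.79, "pct_change": 5.78},
    {"length": 6, "items": ("Ab5", "Ab6", "Ab7", "Ab9", "B4", "B5"),
     "mixing": 0.55, "penalty": 2.90, "r": 0.81, "pct_change": 2.46},
    {"length": 7, "items": ("Ab5", "Ab6", "Ab7", "Ab8", "Ab9", "B4", "B5"),
     "mixing": 0.70, "penalty": 2.05, "r": 0.83, "pct_change": 3.25},
    {"length": 8,
     "items": ("Ab5", "Ab6", "Ab7", "Ab8", "Ab9", "B4", "B5", "B7"),
     "mixing": 0.65, "penalty": 2.25, "r": 0.83, "pct_change": -0.17},
    {"length": 10,
     "items": ("Ab5", "Ab6", "Ab7", "Ab8", "Ab9", "B2", "B4", "B5", "B7",
               "B8"),
     "mixing": 0.50, "penalty": 2.65, "r": 0.88, "pct_change": 5.33},
    {"length": 11,
     "items": ("A10", "Ab5", "Ab6", "Ab7", "Ab8", "Ab9", "B2", "B4", "B5",
               "B7", "B8"),
     "mixing": 0.45, "penalty": 2.95, "r": 0.88, "pct_change": 0.49},
    {"length": 12, "items": FINAL_SHORT_FORM, "mixing": 0.85,
     "penalty": 1.45, "r": 0.90, "pct_change": 2.03},
    {"length": 13,
     "items": ("A10", "Ab5", "Ab6", "Ab7", "Ab8", "Ab9", "Ab11", "B2", "B4",
               "B5", "B7", "B8", "B11"),
     "mixing": 0.40, "penalty": 3.00, "r": 0.91, "pct_change": 0.95},
    {"length": 14,
     "items": ("A8", "A10", "Ab5", "Ab6", "Ab7", "Ab8", "Ab9", "Ab11", "B2",
               "B4", "B5", "B7", "B8", "B11"),
     "mixing": 0.40, "penalty": 2.75, "r": 0.92, "pct_change": 0.77},
    {"length": 15,
     "items": ("A8", "A10", "Ab5", "Ab6", "Ab7", "Ab8", "Ab9", "Ab11",
               "Ab12", "B2", "B4", "B5", "B7", "B8", "B11"),
     "mixing": 0.40, "penalty": 2.30, "r": 0.92, "pct_change": 0.97},
    {"length": 16,
     "items": ("A8", "A10", "Ab1", "Ab5", "Ab6", "Ab7", "Ab8", "Ab9",
               "Ab11", "Ab12", "B2", "B4", "B5", "B7", "B8", "B11"),
     "mixing": 0.55, "penalty": 1.50, "r": 0.93, "pct_change": 0.38},
)


def published_gain_sequence() -> list[tuple[int, float | None]]:
    """The published per-length gain sequence as (length, fractional gain).

    Printed percent changes are converted to fractions (8.34% -> 0.0834);
    the shortest length carries ``None``.
    """
    return [
        (row["length"],
         None if row["pct_change"] is None else row["pct_change"] / 100.0)
        for row in DEVELOPMENT_TABLE_ROWS
    ]


def item_metadata() -> pd.DataFrame:
    """Per-item metadata table: set, domain, practice flag, target proportion.

    Indexed by item id in canonical A -> Ab -> B order.
    """
    records = []
    for item in ITEM_IDS:
        set_label = "Ab" if item.startswith("Ab") else item[0]
        records.append(
            {
                "item_id": item,
                "set_label": set_label,
                "domain_label": DOMAIN_MAP[item],
                "is_practice": item in PRACTICE_ITEMS,
                "target_p": ITEM_PROPORTIONS[item],
            }
        )
    return pd.DataFrame.from_records(records).set_index("item_id")


def set_of(item: str) -> str:
    """Set label (A, Ab or B) of an item id."""
    return "Ab" if item.startswith("Ab") else item[0]


def canonical_sort(items) -> tuple[str, ...]:
    """Sort an item subset into canonical A -> Ab -> B, ascending order."""
    order = {item: k for k, item in enumerate(ITEM_IDS)}
    try:
        return tuple(sorted(items, key=order.__getitem__))
    except KeyError as exc:
        raise KeyError(f"unknown item id: {exc.args[0]!r}") from None
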