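"""Scoring of the standardized usability instruments.

* System Usability Scale (SUS): 10 items scored 1-5; odd items
  contribute (score - 1), even items (5 - score); the sum is scaled by
  2.5 to a 0-100 usability score.
* Attrakdiff 2: 28 bipolar adjective items on -3..3, averaged into four
  subscales (pragmatic quality, hedonic quality identity, hedonic
  quality stimulation, attractiveness) of 7 items each.  The
  item-to-subscale mapping and item polarities ship as an editable data
  file; instrument variants differ in item order, so the default
  mapping (blocks of 7, all positive polarity) can be replaced.
* ISONORM 9241/10: 35 items on -3..3 in 7 categories x 5 items,
  averaged per category.

Likert comparison tables (per-item n/mean/SD for two study arms) are
compared item-by-item with two-tailed summary-statistics t tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .agreement_stats import SummaryTTest, format_p, t_test_from_summary

__all__ = [
    "ISONORM_CATEGORIES",
    "ATTRAKDIFF_SUBSCALES",
    "default_attrakdiff_map",
    "sus_score",
    "attrakdiff_scores",
    "isonorm_scores",
    "compare_likert_tables",
    "score_response_table",
]

ISONORM_CATEGORIES: tuple[str, ...] = (
    "suitability_for_the_task",
    "self_descriptiveness",
    "controllability",
    "conformity_with_user_expectations",
    "error_tolerance",
    "suitability_for_individualization",
    "suitability_for_learning",
)

ATTRAKDIFF_SUBSCALES: tuple[str, ...] = (
    "pragmatic_quality",
    "hedonic_quality_identity",
    "hedonic_quality_stimulation",
    "attractiveness",
)


def default_attrakdiff_map() -> list[dict]:
    """The shipped item -> (subscale, polarity) mapping (28 entries)."""
    with resources.files("bodymap.data").joinpath("attrakdiff_items.json").open(
        "r", encoding="utf-8"
    ) as fh:
        return json.load(fh)


def sus_score(items: Sequence[int]) -> float:
    """SUS score in [0, 100] (a multiple of 2.5) from 10 items scored 1-5."""
    items = list(items)
    if len(items) != 10:
        raise ValueError(f"SUS needs exactly 10 items, got {len(items)}")
    if any(not (1 <= s <= 5) for s in items):
        raise ValueError("SUS item scores must be in 1..5")
    contributions = [
        (s - 1) if i % 2 == 0 else (5 - s)  # 0-based: even index = odd item
        for i, s in enumerate(items)
    ]
    return 2.5 * sum(contributions)


def attrakdiff_scores(
    items: Sequence[float], item_map: list[dict] | None = None
) -> dict[str, float]:
    """Per-subscale means of polarity-adjusted Attrakdiff items (-3..3)."""
    if item_map is None:
        item_map = default_attrakdiff_map()
    items = list(items)
    if len(items) != 28:
        raise ValueError(f"Attrakdiff needs exactly 28 items, got {len(items)}")
    if any(not (-3 <= s <= 3) for s in items):
        raise ValueError("Attrakdiff item scores must be in -3..3")
    mapped_items = {e["item"] for e in item_map}
    if mapped_items != set(range(1, 29)):
        raise ValueError("item_map must assign each of items 1..28 exactly once")
    buckets: dict[str, list[float]] = {s: [] for s in ATTRAKDIFF_SUBSCALES}
    for entry in item_map:
        sub = entry["subscale"]
        if sub not in buckets:
            raise ValueError(f"unknown subscale {sub!r} in item_map")
        buckets[sub].append(entry.get("polarity", 1) * items[entry["item"] - 1])
    return {s: float(np.mean(v)) for s, v in buckets.items()}


def isonorm_scores(items: Sequence[float]) -> dict[str, float]:
    """Per-category means (7 categories x 5 consecutive items, -3..3)."""
    items = list(items)
    if len(items) != 35:
        raise ValueError(f"ISONORM needs exactly 35 items, got {len(items)}")
    if any(not (-3 <= s <= 3) for s in items):
        raise ValueError("ISONORM item scores must be in -3..3")
    return {
        cat: float(np.mean(items[5 * i : 5 * i + 5]))
        for i, cat in enumerate(ISONORM_CATEGORIES)
    }


# ---------------------------------------------------------------------------
# Likert comparison tables
# ---------------------------------------------------------------------------


def _rows_to_frame(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    required = {"item", "n", "mean", "sd"}
    if not required.issubset(df.columns):
        raise ValueError(f"rows need columns {sorted(required)}")
    return df.set_index("item")


def compare_likert_tables(
    study1_rows, study2_rows, variant: str = "pooled", alpha: float = 0.05
) -> pd.DataFrame:
    """Item-wise two-tailed t tests between two study arms given per-item
    summary rows (columns: item, n, mean, sd).  Items must match."""
    a = _rows_to_frame(study1_rows)
    b = _rows_to_frame(study2_rows)
    if list(a.index) != list(b.index):
        raise ValueError("item lists of the two studies do not match")
    out = []
    for item in a.index:
        r = t_test_from_summary(
            a.loc[item, "mean"], a.loc[item, "sd"], int(a.loc[item, "n"]),
            b.loc[item, "mean"], b.loc[item, "sd"], int(b.loc[item, "n"]),
            variant=variant,
        )
        out.append(
            {
                "item": item,
                "mean1": a.loc[item, "mean"], "sd1": a.loc[item, "sd"], "n1": int(a.loc[item, "n"]),
                "mean2": b.loc[item, "mean"], "sd2": b.loc[item, "sd"], "n2": int(b.loc[item, "n"]),
                "t": r.t,
                "df": r.df,
                "p": r.p,
                "p_formatted": format_p(r.p),
                "significant": r.p < alpha,
            }
        )
    return pd.DataFrame(out)


_SCORERS = {
    "sus": lambda row: {"score": sus_score(row)},
    "attrakdiff": lambda row: attrakdiff_scores(row),
    "isonorm": lambda row: isonorm_scores(row),
}

_N_ITEMS = {"sus": 10, "attrakdiff": 28, "isonorm": 35}


def score_response_table(responses: pd.DataFrame, instrument: str) -> pd.DataFrame:
    """Score a table of responses (one row per respondent, one column per
    item, in instrument order) and append group mean and SD rows."""
    if instrument not in _SCORERS:
        raise ValueError(f"unknown instrument {instrument!r}; expected one of {sorted(_SCORERS)}")
    if responses.shape[1] != _N_ITEMS[instrument]:
        raise ValueError(
            f"{instrument} expects {_N_ITEMS[instrument]} item columns, got {responses.shape[1]}"
        )
    scored = pd.DataFrame(
        [_SCORERS[instrument](list(row)) for _, row in responses.iterrows()],
        index=responses.index.astype(str),
    )
    summary = pd.DataFrame(
        [scored.mean(), scored.std(ddof=1)], index=["group_mean", "group_sd"]
    )
    return pd.concat([scored, summary])
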