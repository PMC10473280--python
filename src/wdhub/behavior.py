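"""Distal-simulation vividness composite and group statistics.

Participants rate four aspects of an imagined far-future scenario on a 1-100
sliding scale; the fourth item (difficulty) is reverse-scored. The composite
is the mean of the four (reversed-where-needed) items. Group comparisons use
the pooled-variance two-sample t-test, computable from raw scores or from
printed per-group summary statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .io import SchemaError

logger = logging.getLogger("wdhub")

ITEM_COLUMNS = ["item1", "item2", "item3", "item4"]


class ValidationError(SchemaError):
    """A behavioral record is missing or out of range."""


def reverse_score(x: float, rule: str = "101") -> float:
    """Map a difficulty rating back onto the vividness direction.

    The default rule 101 - x maps the closed 1-100 scale onto itself
    bijectively; the "100" variant (100 - x) suits 0-100 conventions.
    """
    if rule == "101":
        return 101.0 - x
    if rule == "100":
        return 100.0 - x
    raise ValidationError(f"unknown reverse-scoring rule {rule!r}")


def composite_vividness(items, reverse_rule: str = "101") -> float:
    """Mean of the four items after reverse-scoring item 4 (difficulty)."""
    items = list(items)
    if len(items) != 4:
        raise ValidationError(f"expected 4 items, got {len(items)}")
    vals = []
    for k, x in enumerate(items):
        if x is None or (isinstance(x, float) and np.isnan(x)):
            raise ValidationError(f"item {k + 1} is missing")
        x = float(x)
        if not 1.0 <= x <= 100.0:
            raise ValidationError(f"item {k + 1} = {x} outside [1, 100]")
        vals.append(x)
    vals[3] = reverse_score(vals[3], reverse_rule)
    return float(np.mean(vals))


def score_table(table: pd.DataFrame, reverse_rule: str = "101"
                ) -> pd.DataFrame:
    """Add a composite_vividness column; drop records with missing items.

    Dropped records are logged, mirroring a per-analysis missing-data policy
    (a dropped record lowers the t-test df accordingly).
    """
    missing = [c for c in ["subject_id", "group"] + ITEM_COLUMNS
               if c not in table.columns]
    if missing:
        raise SchemaError(f"behavioral table missing columns {missing}")
    usable = table.dropna(subset=ITEM_COLUMNS)
    n_dropped = len(table) - len(usable)
    if n_dropped:
        logger.info("dropped %d behavioral records with missing items",
                    n_dropped)
    out = usable.copy()
    out["composite_vividness"] = [
        composite_vividness(row, reverse_rule)
        for row in usable[ITEM_COLUMNS].to_numpy(dtype=float)
    ]
    return out


@dataclass
class TTestReport:
    t: float
    p: float
    df: int
    mean_1: float
    mean_2: float
    n_1: int
    n_2: int

    def to_dict(self) -> dict:
        return asdict(self)


def group_compare_summary(mean1: float, sd1: float, n1: int,
                          mean2: float, sd2: float, n2: int) -> TTestReport:
    """Pooled two-sample t directly from per-group summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs n >= 2")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (mean1 - mean2) / se
    p = 2.0 * stats.t.sf(abs(t), df=df)
    return TTestReport(t=float(t), p=float(p), df=df,
                       mean_1=float(mean1), mean_2=float(mean2),
                       n_1=n1, n_2=n2)


def group_compare(values_1: np.ndarray, values_2: np.ndarray) -> TTestReport:
    """Pooled two-sample t from raw per-subject scores."""
    x1 = np.asarray(values_1, dtype=float)
    x2 = np.asarray(values_2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValidationError("each group needs n >= 2")
    return group_compare_summary(x1.mean(), x1.std(ddof=1), x1.size,
                                 x2.mean(), x2.std(ddof=1), x2.size)


def group_compare_table(table: pd.DataFrame,
                        value_column: str = "composite_vividness",
                        group_column: str = "group") -> TTestReport:
    """Two-sample t on a scored behavioral table (exactly two groups)."""
    groups = sorted(table[group_column].dropna().unique())
    if len(groups) != 2:
        raise ValidationError(f"expected exactly 2 groups, got {groups}")
    g1 = table.loc[table[group_column] == groups[0], value_column].dropna()
    g2 = table.loc[table[group_column] == groups[1], value_column].dropna()
    return group_compare(g1.to_numpy(), g2.to_numpy())
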