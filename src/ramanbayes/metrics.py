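"""Prediction statistics and histology-vs-probability cross-tabulation."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

from .clustering import ConfusionCounts
from .errors import ValidationError
from .io import VALID_QUINTILES

POSITIVE_CLASS = "tumor"


def _pct(num: int, den: int) -> Fraction | None:
    if den == 0:
        return None
    return Fraction(100 * num, den)


def _display(f: Fraction | None) -> str:
    """Round half-up to 2 decimals for display; 'NA' when undefined."""
    if f is None:
        return "NA"
    d = Decimal(f.numerator) / Decimal(f.denominator)
    return str(d.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class ConfusionStats:
    """Accuracy / sensitivity / specificity with tumor as positive class.

    Ratios are kept exact (rational) internally; ``*_display`` fields are
    half-up-rounded percentages with 2 decimals. A ratio with a zero
    denominator is None / 'NA', never 0.
    """

    TP: int
    FN: int
    TN: int
    FP: int
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    accuracy_display: str
    sensitivity_display: str
    specificity_display: str


def confusion_stats(TP: int, FN: int, TN: int, FP: int) -> ConfusionStats:
    """Exact prediction statistics from 2x2 counts.

    accuracy = 100 (TP+TN)/total, sensitivity = 100 TP/(TP+FN),
    specificity = 100 TN/(TN+FP).
    """
    counts = (TP, FN, TN, FP)
    if any(int(c) != c or c < 0 for c in counts):
        raise ValidationError("confusion counts must be non-negative integers")
    TP, FN, TN, FP = (int(c) for c in counts)
    total = TP + FN + TN + FP
    if total == 0:
        raise ValidationError("confusion counts sum to zero")
    acc = _pct(TP + TN, total)
    sens = _pct(TP, TP + FN)
    spec = _pct(TN, TN + FP)
    return ConfusionStats(
        TP=TP,
        FN=FN,
        TN=TN,
        FP=FP,
        accuracy=None if acc is None else float(acc),
        sensitivity=None if sens is None else float(sens),
        specificity=None if spec is None else float(spec),
        accuracy_display=_display(acc),
        sensitivity_display=_display(sens),
        specificity_display=_display(spec),
    )


def stats_from_counts(counts: ConfusionCounts) -> ConfusionStats:
    return confusion_stats(counts.TP, counts.FN, counts.TN, counts.FP)


@dataclass
class QuintileCrosstab:
    """5x5 histology-quintile x probability-bin count matrix with margins."""

    counts: pd.DataFrame  # index: quintiles 0..100, columns: bins 1..5
    row_margins: pd.Series
    col_margins: pd.Series
    n_included: int
    n_excluded: int

    def to_dict(self) -> dict:
        return {
            "counts": {
                str(q): {str(b): int(self.counts.loc[q, b]) for b in self.counts.columns}
                for q in self.counts.index
            },
            "row_margins": {str(q): int(v) for q, v in self.row_margins.items()},
            "col_margins": {str(b): int(v) for b, v in self.col_margins.items()},
            "n_included": self.n_included,
            "n_excluded": self.n_excluded,
        }


def quintile_crosstab(
    histology: Sequence, bins: Sequence[int]
) -> QuintileCrosstab:
    """Cross-tabulate histology quintiles against probability bins.

    Targets without a histology quintile (None/NaN) are excluded from the
    table and counted in ``n_excluded``.
    """
    if len(histology) != len(bins):
        raise ValidationError("histology and bins differ in length")
    rows = []
    n_excluded = 0
    for q, b in zip(histology, bins):
        if q is None or (isinstance(q, float) and np.isnan(q)):
            n_excluded += 1
            continue
        q = int(q)
        b = int(b)
        if q not in VALID_QUINTILES:
            raise ValidationError(f"invalid histology quintile {q}")
        if not 1 <= b <= 5:
            raise ValidationError(f"invalid probability bin {b}")
        rows.append((q, b))
    table = pd.DataFrame(rows, columns=["quintile", "bin"])
    counts = (
        pd.crosstab(table["quintile"], table["bin"])
        .reindex(index=list(VALID_QUINTILES), columns=[1, 2, 3, 4, 5], fill_value=0)
        .astype(int)
        if len(rows)
        else pd.DataFrame(
            0, index=list(VALID_QUINTILES), columns=[1, 2, 3, 4, 5]
        )
    )
    return QuintileCrosstab(
        counts=counts,
        row_margins=counts.sum(axis=1),
        col_margins=counts.sum(axis=0),
        n_included=len(rows),
        n_excluded=n_excluded,
    )
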