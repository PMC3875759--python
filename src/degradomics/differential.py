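"""Fold-change classification of median-RQ records.

A gene is called tumor-overexpressed when its median RQ exceeds the fold
threshold (default 4, strict inequality), downregulated when the median RQ is
below the reciprocal threshold, and unchanged otherwise.  Inhibitors are
classified like any other gene but tallied separately, and they are excluded
from protease list statistics (ranked top-n lists, compartment counts of
"protease genes").  Non-protease homologues count as proteases.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

from .catalog import Activity, DegradomeCatalog
from .errors import ConfigurationError
from .quant import RQRecord

__all__ = ["Direction", "DifferentialCall", "DifferentialSummary", "classify", "summarize", "top_n"]


class Direction(str, enum.Enum):
    UP = "up"
    DOWN = "down"
    UNCHANGED = "unchanged"


@dataclass(frozen=True)
class DifferentialCall:
    gene: str
    direction: Direction
    median_rq: float
    signed_fold: float
    activity: Activity

    @property
    def is_inhibitor(self) -> bool:
        return self.activity is Activity.INHIBITOR


@dataclass(frozen=True)
class DifferentialSummary:
    n_up_proteases: int
    n_down_proteases: int
    n_up_inhibitors: int
    n_down_inhibitors: int


def classify(
    records: Iterable[RQRecord],
    catalog: DegradomeCatalog,
    threshold: float = 4.0,
) -> list[DifferentialCall]:
    """Apply the strict fold-threshold rule to every record.

    up: median_rq > threshold; down: median_rq < 1/threshold; genes exactly
    at either boundary are unchanged.  Every gene must be annotated in the
    catalog (activity is carried onto the call).
    """
    threshold = float(threshold)
    if threshold <= 1.0:
        raise ConfigurationError(f"fold threshold must be > 1, got {threshold}")
    calls = []
    for rec in records:
        entry = catalog.get(rec.gene)
        if rec.median_rq > threshold:
            direction = Direction.UP
        elif rec.median_rq < 1.0 / threshold:
            direction = Direction.DOWN
        else:
            direction = Direction.UNCHANGED
        calls.append(
            DifferentialCall(
                gene=entry.symbol,
                direction=direction,
                median_rq=rec.median_rq,
                signed_fold=rec.signed_fold,
                activity=entry.activity,
            )
        )
    return calls


def summarize(calls: Iterable[DifferentialCall]) -> DifferentialSummary:
    """Count up/down calls, splitting proteases (incl. NPH) from inhibitors."""
    n_up_p = n_down_p = n_up_i = n_down_i = 0
    for call in calls:
        if call.direction is Direction.UP:
            if call.is_inhibitor:
                n_up_i += 1
            else:
                n_up_p += 1
        elif call.direction is Direction.DOWN:
            if call.is_inhibitor:
                n_down_i += 1
            else:
                n_down_p += 1
    return DifferentialSummary(n_up_p, n_down_p, n_up_i, n_down_i)


def top_n(
    calls: Iterable[DifferentialCall], direction: Direction | str, n: int
) -> list[str]:
    """Ranked protease list for one direction.

    Proteases only (inhibitors excluded), sorted by |signed fold| descending
    with alphabetical tie-break; returns at most ``n`` symbols without
    padding.
    """
    direction = Direction(direction)
    if direction is Direction.UNCHANGED:
        raise ConfigurationError("top_n direction must be 'up' or 'down'")
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    eligible = [
        c for c in calls if c.direction is direction and not c.is_inhibitor
    ]
    eligible.sort(key=lambda c: (-abs(c.signed_fold), c.gene))
    return [c.gene for c in eligible[:n]]
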