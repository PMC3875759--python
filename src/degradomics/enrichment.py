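"""Localization enrichment and somatic-mutation cross-referencing.

Two inference steps sit downstream of classification:

* **Localization enrichment** — is a differential gene list skewed toward the
  extracellular compartment relative to the composition of the profiling
  arrays?  The 2x2 table puts the list's (extracellular, intracellular)
  counts in row 1 and the remaining background probes in row 2; significance
  is the two-sided Fisher exact p.  The background is either the array
  content or the set of probes expressed in the reference tissue.

* **Mutation cross-referencing** — intersect a ranked top-n protease list
  with a catalog of somatically mutated genes, reporting hits in rank order
  and the hit proportion on the declared n denominator (even when fewer than
  n list members are known, which keeps proportions comparable when lists
  are reconstructed from published excerpts).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .catalog import DegradomeCatalog
from .differential import Direction, DifferentialCall, top_n
from .errors import ConfigurationError, ValidationError
from .stats import ContingencyTable2x2, Sidedness, TestResult, fisher_exact, proportion_test_one_sided

__all__ = [
    "Background",
    "EnrichmentResult",
    "MutationCatalog",
    "XrefResult",
    "localization_enrichment",
    "cross_reference",
    "cross_reference_symbols",
    "compare_mutation_proportions",
    "mean_transcript_length",
]


class Background(str, enum.Enum):
    ARRAY_CONTENT = "array_content"
    EXPRESSED_IN_TISSUE = "expressed_in_tissue"


@dataclass(frozen=True)
class EnrichmentResult:
    list_counts: tuple[int, int]  # (extracellular, intracellular)
    background_used: Background
    table: ContingencyTable2x2
    p_two_sided: float
    direction: str | None = None


@dataclass(frozen=True)
class MutationCatalog:
    """A named set of somatically mutated gene symbols (case-insensitive)."""

    name: str
    symbols: frozenset[str]

    def __post_init__(self) -> None:
        cleaned = frozenset(
            s.strip().upper() for s in self.symbols if s and s.strip()
        )
        object.__setattr__(self, "symbols", cleaned)

    def __contains__(self, symbol: str) -> bool:
        return str(symbol).strip().upper() in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class XrefResult:
    direction: str
    top_n: int
    hits: tuple[str, ...]
    proportion: float  # percentage on the top_n denominator
    catalog_name: str = ""
    comparison_p: float | None = None
    mean_transcript_length: float | None = None


def localization_enrichment(
    symbols: Iterable[str],
    catalog: DegradomeCatalog,
    background: Background | str = Background.ARRAY_CONTENT,
    direction: str | None = None,
) -> EnrichmentResult:
    """Two-sided Fisher test of a list's compartment split against background.

    Builds ``[[list_EC, list_IC], [bg_EC - list_EC, bg_IC - list_IC]]`` so
    the rows are disjoint (the list is a subset of the probe universe).
    """
    background = Background(background)
    bg = (
        catalog.array_background
        if background is Background.ARRAY_CONTENT
        else catalog.expressed_background
    )
    if bg is None:
        raise ConfigurationError(
            f"catalog carries no {background.value} background counts"
        )
    n_ec, n_ic = catalog.compartment_counts(symbols)
    if n_ec > bg[0] or n_ic > bg[1]:
        raise ValidationError(
            f"list compartment counts ({n_ec}, {n_ic}) exceed the "
            f"{background.value} background {bg}"
        )
    table = ContingencyTable2x2(n_ec, n_ic, bg[0] - n_ec, bg[1] - n_ic)
    res = fisher_exact(table, Sidedness.TWO_SIDED)
    return EnrichmentResult(
        list_counts=(n_ec, n_ic),
        background_used=background,
        table=table,
        p_two_sided=res.p_value,
        direction=direction,
    )


def cross_reference_symbols(
    ranked_symbols: Sequence[str],
    n: int,
    catalog: MutationCatalog,
    direction: str = "",
) -> XrefResult:
    """Intersect a ranked symbol list with a mutation catalog.

    ``n`` is the declared list size and the proportion denominator; hits are
    reported in rank order with set semantics on the catalog.
    """
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    top = list(ranked_symbols)[:n]
    hits = tuple(s for s in top if s in catalog)
    return XrefResult(
        direction=direction,
        top_n=n,
        hits=hits,
        proportion=100.0 * len(hits) / n,
        catalog_name=catalog.name,
    )


def cross_reference(
    calls: Iterable[DifferentialCall],
    direction: Direction | str,
    n: int,
    catalog: MutationCatalog,
) -> XrefResult:
    """Cross-reference the top-n protease list of one direction."""
    direction = Direction(direction)
    ranked = top_n(calls, direction, n)
    return cross_reference_symbols(ranked, n, catalog, direction=direction.value)


def compare_mutation_proportions(
    xref_down: XrefResult, xref_up: XrefResult
) -> TestResult:
    """One-sided test that the down-list hit proportion exceeds the up-list's.

    Pooled two-proportion z with the companion one-sided Fisher p (see
    ``stats.proportion_test_one_sided``); both lists must declare the same n.
    """
    if xref_down.top_n != xref_up.top_n:
        raise ConfigurationError(
            f"list sizes differ: {xref_down.top_n} vs {xref_up.top_n}"
        )
    n = xref_down.top_n
    return proportion_test_one_sided(len(xref_down.hits), n, len(xref_up.hits), n)


def mean_transcript_length(
    symbols: Iterable[str], catalog: DegradomeCatalog
) -> float:
    """Arithmetic mean transcript length (bp) over annotated symbols.

    Genes without a recorded length are excluded with a warning stating how
    many were skipped; having no lengths at all is an error.
    """
    lengths = []
    n_missing = 0
    for s in symbols:
        length = catalog.get(s).transcript_length_bp
        if length is None:
            n_missing += 1
        else:
            lengths.append(length)
    if not lengths:
        raise ValidationError("no transcript lengths available for the given symbols")
    if n_missing:
        warnings.warn(
            f"mean_transcript_length: {n_missing} gene(s) lacked a length and were excluded",
            stacklevel=2,
        )
    return float(np.mean(lengths))
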