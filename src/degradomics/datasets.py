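"""Packaged reference fixtures.

The package ships the published colorectal degradome results as plain-text
fixtures: the differential table (median-RQ magnitudes, localization and
activity per gene, plus the array compartment backgrounds), the known
members of the two top-50 protease lists, and the mutation-catalog excerpts
used for cross-referencing.  These let the classification, enrichment and
cross-referencing stages run end-to-end without raw Ct plates (which were
never deposited).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .catalog import DegradomeCatalog, load_catalog
from .enrichment import MutationCatalog
from .quant import RQRecord, signed_fold

__all__ = [
    "table1_catalog",
    "table1_rq_records",
    "top50_list",
    "mutation_catalog",
    "fixture_path",
]


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture (data/<name>)."""
    return Path(resources.files("degradomics.data") / name)


def table1_catalog() -> DegradomeCatalog:
    """The published differential-gene catalog with array backgrounds."""
    return load_catalog(fixture_path("table1.tsv"))


def table1_rq_records() -> list[RQRecord]:
    """Per-gene median RQ from the published table (precomputed-RQ mode).

    The table prints fold magnitudes per direction; the down-section RQ is
    the reciprocal of the printed magnitude.  No per-patient values are
    available, so ``per_patient_rq`` is empty.
    """
    df = pd.read_csv(fixture_path("table1.tsv"), sep="\t", comment="#", dtype=str)
    records = []
    for _, row in df.iterrows():
        magnitude = float(row["fold"])
        rq = magnitude if row["direction"] == "up" else 1.0 / magnitude
        records.append(
            RQRecord(gene=row["symbol"], median_rq=rq, signed_fold=signed_fold(rq))
        )
    return records


def _read_symbol_lines(name: str) -> list[str]:
    lines = fixture_path(name).read_text(encoding="utf-8").splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]


def top50_list(direction: str) -> list[str]:
    """Known members of the top-50 protease list for a direction.

    Partial reconstructions (24/50 up, 36/50 down): only published members
    are carried, in published rank order where known.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    return _read_symbol_lines(f"top50_{direction}.txt")


def mutation_catalog(name: str) -> MutationCatalog:
    """Packaged somatic-mutation catalog excerpt: 'colon' or 'breast'."""
    if name not in ("colon", "breast"):
        raise ValueError(f"no packaged mutation catalog named {name!r}")
    return MutationCatalog(name=name, symbols=frozenset(_read_symbol_lines(f"mutations_{name}.txt")))
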