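"""Degradome annotation catalog.

A degradome catalog maps protease / protease-inhibitor gene symbols to a
subcellular localization class (secreted, membrane-bound, or intracellular),
an activity class (catalytically active protease, inhibitor, or non-protease
homologue), and optionally a catalytic class and transcript length.  The
catalog also carries the compartment composition of the profiling arrays
(extracellular vs intracellular probe counts) used as the null universe for
localization enrichment, plus an optional "expressed in reference tissue"
background.

Localization enrichment collapses the two extracellular classes (secreted
EC-S and transmembrane EC-TM) into a single extracellular compartment;
``compartment`` implements that collapse.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import FormatError, UnknownGeneError, ValidationError

__all__ = [
    "Localization",
    "Activity",
    "CatalyticClass",
    "ProteaseGene",
    "DegradomeCatalog",
    "compartment",
    "compartment_counts",
    "load_catalog",
    "write_catalog",
]


class Localization(str, enum.Enum):
    """Subcellular localization of the gene product."""

    EC_S = "EC-S"  # extracellular, secreted
    EC_TM = "EC-TM"  # extracellular, membrane-anchored
    IC = "IC"  # intracellular

    @classmethod
    def parse(cls, value: str) -> "Localization":
        v = str(value).strip().upper().replace("_", "-")
        for member in cls:
            if member.value.upper() == v:
                return member
        raise ValidationError(
            f"unknown localization {value!r}; expected one of "
            f"{[m.value for m in cls]}"
        )


class Activity(str, enum.Enum):
    PROTEASE = "protease"
    INHIBITOR = "inhibitor"
    NPH = "NPH"  # non-protease homologue; counted with proteases in list stats

    @classmethod
    def parse(cls, value: str) -> "Activity":
        v = str(value).strip().lower()
        for member in cls:
            if member.value.lower() == v:
                return member
        raise ValidationError(
            f"unknown activity {value!r}; expected one of "
            f"{[m.value for m in cls]}"
        )


class CatalyticClass(str, enum.Enum):
    ASPARTYL = "aspartyl"
    CYSTEINE = "cysteine"
    METALLO = "metallo"
    SERINE = "serine"
    THREONINE = "threonine"
    INHIBITOR = "inhibitor"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, value: str) -> "CatalyticClass":
        v = str(value).strip().lower()
        for member in cls:
            if member.value == v:
                return member
        raise ValidationError(f"unknown catalytic class {value!r}")


@dataclass(frozen=True)
class ProteaseGene:
    """One catalog entry.

    ``transcript_length_bp`` is optional because the source annotation does
    not provide lengths for every gene; operations that need lengths report
    how many entries were skipped.
    """

    symbol: str
    localization: Localization
    activity: Activity
    catalytic_class: CatalyticClass | None = None
    transcript_length_bp: int | None = None

    def __post_init__(self) -> None:
        if not self.symbol or not str(self.symbol).strip():
            raise ValidationError("gene symbol must be nonempty")
        object.__setattr__(self, "symbol", str(self.symbol).strip())
        if not isinstance(self.localization, Localization):
            object.__setattr__(
                self, "localization", Localization.parse(self.localization)
            )
        if not isinstance(self.activity, Activity):
            object.__setattr__(self, "activity", Activity.parse(self.activity))
        if self.catalytic_class is not None and not isinstance(
            self.catalytic_class, CatalyticClass
        ):
            object.__setattr__(
                self, "catalytic_class", CatalyticClass.parse(self.catalytic_class)
            )
        if self.transcript_length_bp is not None:
            length = int(self.transcript_length_bp)
            if length <= 0:
                raise ValidationError(
                    f"{self.symbol}: transcript_length_bp must be > 0, got {length}"
                )
            object.__setattr__(self, "transcript_length_bp", length)

    @property
    def is_inhibitor(self) -> bool:
        return self.activity is Activity.INHIBITOR


def compartment(gene: ProteaseGene) -> str:
    """Collapse the three localization classes into two compartments.

    EC-S and EC-TM are both ``"extracellular"``; IC is ``"intracellular"``.
    """
    if gene.localization in (Localization.EC_S, Localization.EC_TM):
        return "extracellular"
    return "intracellular"


@dataclass
class DegradomeCatalog:
    """An annotated gene set plus the array-composition backgrounds.

    The catalog holds only the genes the pipeline touches; the full probe
    universe of the arrays is represented by ``array_background``, the
    (extracellular, intracellular) probe counts, and optionally by
    ``expressed_background``, the compartment counts of probes expressed in
    the reference tissue.  Symbols are matched case-insensitively after
    trimming; no alias resolution is attempted.
    """

    entries: tuple[ProteaseGene, ...]
    array_background: tuple[int, int] | None = None
    expressed_background: tuple[int, int] | None = None
    _index: dict[str, ProteaseGene] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.entries = tuple(self.entries)
        index: dict[str, ProteaseGene] = {}
        dupes = []
        for g in self.entries:
            key = g.symbol.upper()
            if key in index:
                dupes.append(g.symbol)
            index[key] = g
        if dupes:
            raise ValidationError(f"duplicate gene symbols in catalog: {sorted(set(dupes))}")
        self._index = index
        for name in ("array_background", "expressed_background"):
            bg = getattr(self, name)
            if bg is None:
                continue
            bg = (int(bg[0]), int(bg[1]))
            if min(bg) < 0:
                raise ValidationError(f"{name} counts must be nonnegative: {bg}")
            setattr(self, name, bg)
        if self.array_background is not None:
            own = self.compartment_counts([g.symbol for g in self.entries])
            if own[0] > self.array_background[0] or own[1] > self.array_background[1]:
                raise ValidationError(
                    "array_background smaller than the catalog's own compartment "
                    f"counts: background {self.array_background}, entries {own}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, symbol: str) -> bool:
        return str(symbol).strip().upper() in self._index

    def __iter__(self):
        return iter(self.entries)

    def get(self, symbol: str) -> ProteaseGene:
        key = str(symbol).strip().upper()
        try:
            return self._index[key]
        except KeyError:
            raise UnknownGeneError(symbol) from None

    def symbols(self) -> list[str]:
        return [g.symbol for g in self.entries]

    def compartment_counts(self, symbols: Iterable[str]) -> tuple[int, int]:
        """(n_extracellular, n_intracellular) over ``symbols``.

        Order-independent; every symbol must be present in the catalog.
        """
        n_ec = n_ic = 0
        for s in symbols:
            if compartment(self.get(s)) == "extracellular":
                n_ec += 1
            else:
                n_ic += 1
        return n_ec, n_ic


def compartment_counts(
    symbols: Iterable[str], catalog: DegradomeCatalog
) -> tuple[int, int]:
    """Module-level alias for :meth:`DegradomeCatalog.compartment_counts`."""
    return catalog.compartment_counts(symbols)


_REQUIRED_COLUMNS = ("symbol", "localization", "activity")
_OPTIONAL_COLUMNS = ("catalytic_class", "transcript_length_bp")
_DIRECTIVE_PREFIX = "#%"


def _parse_directives(path: Path) -> dict[str, tuple[int, int]]:
    """Read ``#% key<TAB>ec<TAB>ic`` metadata lines (backgrounds)."""
    directives: dict[str, tuple[int, int]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith(_DIRECTIVE_PREFIX):
                parts = line[len(_DIRECTIVE_PREFIX):].split()
                if len(parts) != 3:
                    raise FormatError(f"malformed directive line: {line.strip()!r}")
                key, ec, ic = parts
                directives[key] = (int(ec), int(ic))
    return directives


def load_catalog(path: str | Path) -> DegradomeCatalog:
    """Read a catalog TSV.

    Dialect: tab-separated, UTF-8, required columns ``symbol, localization,
    activity``; optional ``catalytic_class`` and ``transcript_length_bp``;
    extra columns ignored; ``#``-prefixed comment lines ignored, except
    ``#%`` directive lines which carry the background counts, e.g.::

        #% array_background  266  264
        #% expressed_background  219  255
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    directives = _parse_directives(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"catalog file {path} is missing required column(s): {missing}")
    entries = []
    for _, row in df.iterrows():
        cat = row.get("catalytic_class")
        length = row.get("transcript_length_bp")
        entries.append(
            ProteaseGene(
                symbol=row["symbol"],
                localization=row["localization"],
                activity=row["activity"],
                catalytic_class=None if _blank(cat) else cat,
                transcript_length_bp=None if _blank(length) else int(float(length)),
            )
        )
    return DegradomeCatalog(
        entries=tuple(entries),
        array_background=directives.get("array_background"),
        expressed_background=directives.get("expressed_background"),
    )


def _blank(value) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value)) or str(value).strip() == ""


def write_catalog(catalog: DegradomeCatalog, path: str | Path) -> None:
    """Write a catalog in the TSV dialect read by :func:`load_catalog`."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for name in ("array_background", "expressed_background"):
            bg = getattr(catalog, name)
            if bg is not None:
                fh.write(f"{_DIRECTIVE_PREFIX} {name}\t{bg[0]}\t{bg[1]}\n")
        fh.write("\t".join(_REQUIRED_COLUMNS + _OPTIONAL_COLUMNS) + "\n")
        for g in catalog.entries:
            fh.write(
                "\t".join(
                    [
                        g.symbol,
                        g.localization.value,
                        g.activity.value,
                        "" if g.catalytic_class is None else g.catalytic_class.value,
                        "" if g.transcript_length_bp is None else str(g.transcript_length_bp),
                    ]
                )
                + "\n"
            )
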