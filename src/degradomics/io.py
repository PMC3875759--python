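"""File dialects, sample QC, and the end-to-end pipeline.

All tabular inputs and outputs are tab-separated UTF-8 text with a header
row; structured reports are JSON.  The Ct table dialect is::

    sample_id  patient_id  tissue  gene  ct  [rin]

with ``tissue`` in {tumor, normal} and ``Undetermined`` (case-insensitive)
accepted in ``ct``.  A precomputed-RQ mode accepts a per-gene median-RQ
table instead of raw plates, so classification/enrichment/cross-referencing
can run on published summary tables.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import datasets
from .catalog import DegradomeCatalog, load_catalog
from .differential import Direction, classify, summarize, top_n
from .enrichment import (
    Background,
    MutationCatalog,
    compare_mutation_proportions,
    cross_reference,
    localization_enrichment,
)
from .errors import FormatError, ValidationError
from .quant import CtDataset, CtMeasurement, PairedSample, RQRecord, quantify, signed_fold

__all__ = [
    "read_ct_table",
    "write_ct_table",
    "read_rq_table",
    "write_rq_table",
    "read_mutation_list",
    "qc_filter_samples",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger("degradomics")

_CT_COLUMNS = ("sample_id", "patient_id", "tissue", "gene", "ct")


def read_ct_table(
    path: str | Path,
    reference_genes: list[str],
    max_cycles: float = 40.0,
) -> CtDataset:
    """Read a long-format Ct table into a paired dataset.

    Pairs are assembled from (patient_id, tissue); each patient must have
    exactly one tumor and one normal sample.  Malformed Ct values are
    reported with their line number (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _CT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"Ct table {path} is missing required column(s): {missing}")
    has_rin = "rin" in df.columns

    measurements = []
    sample_meta: dict[str, tuple[str, str, float | None]] = {}
    for i, row in df.iterrows():
        line_no = i + 2  # header occupies line 1
        raw_ct = str(row["ct"]).strip()
        if raw_ct.lower() == "undetermined":
            ct = None
        else:
            try:
                ct = float(raw_ct)
            except ValueError:
                raise FormatError(
                    f"{path}: malformed Ct value {raw_ct!r} on line {line_no}"
                ) from None
        tissue = str(row["tissue"]).strip().lower()
        if tissue not in ("tumor", "normal"):
            raise FormatError(
                f"{path}: tissue must be 'tumor' or 'normal' on line {line_no}, "
                f"got {row['tissue']!r}"
            )
        sid = str(row["sample_id"]).strip()
        measurements.append(CtMeasurement(sid, str(row["gene"]).strip(), ct))
        rin = None
        if has_rin and not pd.isna(row["rin"]) and str(row["rin"]).strip():
            rin = float(row["rin"])
        prev = sample_meta.get(sid)
        if prev is not None and prev[:2] != (str(row["patient_id"]).strip(), tissue):
            raise FormatError(
                f"{path}: sample {sid!r} has inconsistent patient/tissue on line {line_no}"
            )
        sample_meta[sid] = (str(row["patient_id"]).strip(), tissue, rin if rin is not None else (prev[2] if prev else None))

    by_patient: dict[str, dict[str, tuple[str, float | None]]] = {}
    for sid, (pid, tissue, rin) in sample_meta.items():
        slot = by_patient.setdefault(pid, {})
        if tissue in slot:
            raise FormatError(f"{path}: patient {pid!r} has two {tissue} samples")
        slot[tissue] = (sid, rin)
    pairs = []
    for pid, slot in sorted(by_patient.items()):
        if set(slot) != {"tumor", "normal"}:
            raise FormatError(
                f"{path}: patient {pid!r} lacks a matched tumor/normal pair"
            )
        pairs.append(
            PairedSample(
                patient_id=pid,
                tumor_sample_id=slot["tumor"][0],
                normal_sample_id=slot["normal"][0],
                rin_tumor=slot["tumor"][1],
                rin_normal=slot["normal"][1],
            )
        )
    return CtDataset(measurements, pairs, reference_genes, max_cycles=max_cycles)


def write_ct_table(dataset: CtDataset, path: str | Path) -> None:
    """Write a dataset back to the Ct table dialect (lossless for fixtures)."""
    tissue_of = {}
    patient_of = {}
    rin_of = {}
    for p in dataset.pairs:
        tissue_of[p.tumor_sample_id] = "tumor"
        tissue_of[p.normal_sample_id] = "normal"
        patient_of[p.tumor_sample_id] = p.patient_id
        patient_of[p.normal_sample_id] = p.patient_id
        rin_of[p.tumor_sample_id] = p.rin_tumor
        rin_of[p.normal_sample_id] = p.rin_normal
    has_rin = any(v is not None for v in rin_of.values())
    with open(path, "w", encoding="utf-8") as fh:
        cols = list(_CT_COLUMNS) + (["rin"] if has_rin else [])
        fh.write("\t".join(cols) + "\n")
        for m in dataset.measurements:
            ct = "Undetermined" if m.ct is None else repr(m.ct)
            row = [
                m.sample_id,
                patient_of.get(m.sample_id, ""),
                tissue_of.get(m.sample_id, ""),
                m.gene,
                ct,
            ]
            if has_rin:
                rin = rin_of.get(m.sample_id)
                row.append("" if rin is None else repr(rin))
            fh.write("\t".join(row) + "\n")


def read_rq_table(path: str | Path) -> list[RQRecord]:
    """Precomputed-RQ mode: read per-gene median RQ (or signed fold).

    Accepts either a ``median_rq`` column or a ``signed_fold`` column
    (converted via RQ = fold if fold >= 1 else -1/fold); gene symbols come
    from a ``gene`` or ``symbol`` column.
    """
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    gene_col = "gene" if "gene" in df.columns else "symbol"
    if gene_col not in df.columns:
        raise FormatError(f"{path}: need a 'gene' or 'symbol' column")
    records = []
    for _, row in df.iterrows():
        if "median_rq" in df.columns:
            rq = float(row["median_rq"])
        elif "signed_fold" in df.columns:
            fold = float(row["signed_fold"])
            rq = fold if fold >= 1 else -1.0 / fold
        else:
            raise FormatError(f"{path}: need a 'median_rq' or 'signed_fold' column")
        records.append(RQRecord(gene=str(row[gene_col]), median_rq=rq, signed_fold=signed_fold(rq)))
    return records


def write_rq_table(records: list[RQRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tmedian_rq\tsigned_fold\tn_informative_pairs\n")
        for r in records:
            fh.write(
                f"{r.gene}\t{r.median_rq!r}\t{r.signed_fold!r}\t{r.n_informative_pairs}\n"
            )


def read_mutation_list(path: str | Path, name: str | None = None) -> MutationCatalog:
    """One symbol per line, or a TSV with a ``symbol`` column; '#' comments."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if lines and "\t" in lines[0] or (lines and lines[0].lower() == "symbol"):
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        if "symbol" not in df.columns:
            raise FormatError(f"{path}: mutation TSV needs a 'symbol' column")
        symbols = frozenset(df["symbol"].dropna().astype(str))
    else:
        symbols = frozenset(lines)
    return MutationCatalog(name=name or path.stem, symbols=symbols)


def qc_filter_samples(
    dataset: CtDataset, rin_min: float = 7.0
) -> tuple[CtDataset, list[dict]]:
    """Drop pairs whose tumor or normal RNA falls below the RIN threshold.

    The design is paired, so either member failing excludes the whole pair
    (and both samples' measurements).  The inclusive rule retains RIN ==
    rin_min exactly.  Pairs with missing RIN pass with a warning.
    """
    if not (1.0 <= rin_min <= 10.0):
        raise ValidationError(f"rin_min must lie in [1, 10], got {rin_min}")
    kept_pairs = []
    report = []
    for p in dataset.pairs:
        reasons = []
        for label, rin in (("tumor", p.rin_tumor), ("normal", p.rin_normal)):
            if rin is None:
                warnings.warn(
                    f"patient {p.patient_id}: missing {label} RIN, retained",
                    stacklevel=2,
                )
            elif rin < rin_min:
                reasons.append(f"{label} RIN {rin} < {rin_min}")
        if reasons:
            report.append({"patient_id": p.patient_id, "reasons": reasons})
        else:
            kept_pairs.append(p)
    kept_samples = {s for p in kept_pairs for s in (p.tumor_sample_id, p.normal_sample_id)}
    kept_measurements = [m for m in dataset.measurements if m.sample_id in kept_samples]
    if not kept_pairs:
        raise ValidationError("QC excluded every pair; nothing to analyze")
    filtered = CtDataset(
        kept_measurements, kept_pairs, dataset.reference_genes, dataset.max_cycles
    )
    return filtered, report


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    ct_table: str | None = None
    rq_table: str | None = None  # precomputed-RQ mode
    catalog_path: str | None = None  # None -> packaged differential catalog
    mutation_catalogs: dict[str, str] = field(default_factory=dict)
    reference_genes: list[str] = field(default_factory=list)
    threshold: float = 4.0
    background: str = Background.ARRAY_CONTENT.value
    top_n: int = 50
    rin_min: float = 7.0
    max_cycles: float = 40.0
    apply_rin_filter: bool = True
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.threshold <= 1:
            raise ValidationError(f"threshold must be > 1, got {self.threshold}")
        if not (1.0 <= self.rin_min <= 10.0):
            raise ValidationError(f"rin_min must lie in [1, 10], got {self.rin_min}")
        if self.ct_table is None and self.rq_table is None:
            raise ValidationError("provide either ct_table or rq_table")


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """qc -> quantify -> classify -> enrich -> cross-reference.

    Returns the report dict; when ``config.out_dir`` is set, also writes
    ``differential.tsv``, ``rq.tsv`` (raw-Ct mode) and ``report.json``.
    Deterministic given the config (no randomness in the analysis path).
    """
    report: dict = {"config": {k: v for k, v in asdict(config).items()}}

    with _stage("catalog"):
        catalog = (
            load_catalog(config.catalog_path)
            if config.catalog_path
            else datasets.table1_catalog()
        )

    if config.rq_table is not None:
        with _stage("load_rq"):
            records = read_rq_table(config.rq_table)
        report["mode"] = "precomputed_rq"
        report["qc"] = {"applied": False}
    else:
        with _stage("load_ct"):
            dataset = read_ct_table(
                config.ct_table, config.reference_genes, config.max_cycles
            )
        if config.apply_rin_filter:
            with _stage("qc"):
                dataset, exclusions = qc_filter_samples(dataset, config.rin_min)
            report["qc"] = {
                "applied": True,
                "rin_min": config.rin_min,
                "n_pairs_retained": len(dataset.pairs),
                "exclusions": exclusions,
            }
        else:
            report["qc"] = {"applied": False}
        with _stage("quantify"):
            records, not_evaluable = quantify(dataset)
        report["mode"] = "raw_ct"
        report["not_evaluable_genes"] = not_evaluable

    with _stage("classify"):
        calls = classify(records, catalog, threshold=config.threshold)
        counts = summarize(calls)
    report["summary"] = asdict(counts)
    report["threshold"] = config.threshold

    with _stage("enrich"):
        enrichment = {}
        for direction in (Direction.UP, Direction.DOWN):
            members = [
                c.gene for c in calls
                if c.direction is direction and not c.is_inhibitor
            ]
            if not members:
                continue
            res = localization_enrichment(
                members, catalog, config.background, direction=direction.value
            )
            enrichment[direction.value] = {
                "list_counts": list(res.list_counts),
                "background": res.background_used.value,
                "table": [[res.table.a, res.table.b], [res.table.c, res.table.d]],
                "p_two_sided": res.p_two_sided,
                "method": "fisher_exact two-sided",
            }
    report["enrichment"] = enrichment

    if config.mutation_catalogs:
        with _stage("xref"):
            xref_report = {}
            for name, mpath in config.mutation_catalogs.items():
                mcat = read_mutation_list(mpath, name)
                per_dir = {}
                results = {}
                for direction in (Direction.UP, Direction.DOWN):
                    xr = cross_reference(calls, direction, config.top_n, mcat)
                    results[direction] = xr
                    per_dir[direction.value] = {
                        "hits": list(xr.hits),
                        "n_hits": len(xr.hits),
                        "proportion_pct": xr.proportion,
                        "top_n": xr.top_n,
                    }
                comp = compare_mutation_proportions(
                    results[Direction.DOWN], results[Direction.UP]
                )
                per_dir["down_vs_up"] = {
                    "method": comp.method,
                    "z": comp.statistic,
                    "p_one_sided": comp.p_value,
                    "fisher_one_sided_p": comp.extra["fisher_one_sided_p"],
                }
                xref_report[name] = per_dir
        report["xref"] = xref_report

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "differential.tsv", "w", encoding="utf-8") as fh:
            fh.write("gene\tdirection\tmedian_rq\tsigned_fold\tactivity\n")
            for c in calls:
                fh.write(
                    f"{c.gene}\t{c.direction.value}\t{c.median_rq!r}\t"
                    f"{c.signed_fold!r}\t{c.activity.value}\n"
                )
        if config.rq_table is None:
            write_rq_table(records, out / "rq.tsv")
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report
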