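"""Relative quantification of paired tumor/normal qPCR data.

The pipeline uses the ideal-efficiency comparative-Ct model: within a sample
a target's Ct is normalized against the mean Ct of declared reference genes
(dCt), the paired tumor and normal dCt values are differenced (ddCt), and the
relative quantity is RQ = 2^-ddCt.  Per-gene estimates are aggregated across
patients as the median RQ, reported alongside the signed-fold display
transform (RQ if RQ >= 1, else -1/RQ).

Undetermined Ct values (no amplification before the last cycle) are handled
with a censoring policy: if exactly one member of a pair is undetermined for
a gene it is imputed at ``max_cycles`` so the fold change keeps its direction
without becoming infinite; if both members are undetermined the pair is
non-informative for that gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import NotEvaluableError, ValidationError

__all__ = [
    "UNDETERMINED",
    "CtMeasurement",
    "PairedSample",
    "CtDataset",
    "RQRecord",
    "delta_ct",
    "rq_for_pair",
    "median_rq",
    "quantify",
    "signed_fold",
    "detection_rate",
]

#: Sentinel for a Ct that never crossed the detection threshold.
UNDETERMINED = None


@dataclass(frozen=True)
class CtMeasurement:
    """One well: a (sample, gene) threshold-cycle reading.

    ``ct`` is ``None`` (UNDETERMINED) when the probe never crossed the
    fluorescence threshold.
    """

    sample_id: str
    gene: str
    ct: float | None

    def __post_init__(self) -> None:
        if self.ct is not None:
            ct = float(self.ct)
            if not math.isfinite(ct) or ct <= 0:
                raise ValidationError(
                    f"{self.sample_id}/{self.gene}: determined Ct must be finite "
                    f"and positive, got {self.ct!r}"
                )
            object.__setattr__(self, "ct", ct)


@dataclass(frozen=True)
class PairedSample:
    """A patient's matched tumor and normal-mucosa samples."""

    patient_id: str
    tumor_sample_id: str
    normal_sample_id: str
    rin_tumor: float | None = None
    rin_normal: float | None = None

    def __post_init__(self) -> None:
        if self.tumor_sample_id == self.normal_sample_id:
            raise ValidationError(
                f"patient {self.patient_id}: tumor and normal sample ids must differ"
            )
        for name in ("rin_tumor", "rin_normal"):
            rin = getattr(self, name)
            if rin is not None and not (1.0 <= float(rin) <= 10.0):
                raise ValidationError(
                    f"patient {self.patient_id}: {name} must be in [1, 10], got {rin}"
                )


class CtDataset:
    """Ct measurements plus the pairing design and reference-gene set.

    Parameters
    ----------
    measurements
        Collection of :class:`CtMeasurement`.
    pairs
        One :class:`PairedSample` per patient.
    reference_genes
        Nonempty list of endogenous-control gene symbols; their per-sample
        mean Ct anchors dCt.
    max_cycles
        Last PCR cycle; also the imputation value for censored readings.
    """

    def __init__(
        self,
        measurements: Iterable[CtMeasurement],
        pairs: Iterable[PairedSample],
        reference_genes: Sequence[str],
        max_cycles: float = 40.0,
    ):
        self.measurements = tuple(measurements)
        self.pairs = tuple(pairs)
        self.reference_genes = tuple(str(g) for g in reference_genes)
        self.max_cycles = float(max_cycles)
        if not self.reference_genes:
            raise ValidationError("reference_genes must be nonempty")
        if self.max_cycles <= 0:
            raise ValidationError("max_cycles must be positive")
        self._ct: dict[tuple[str, str], float | None] = {}
        for m in self.measurements:
            self._ct[(m.sample_id, m.gene)] = m.ct
        self._ref_mean: dict[str, float] = {}
        sample_ids = {m.sample_id for m in self.measurements}
        for p in self.pairs:
            for sid in (p.tumor_sample_id, p.normal_sample_id):
                if sid not in sample_ids:
                    raise ValidationError(
                        f"pair {p.patient_id}: sample {sid!r} has no measurements"
                    )
                for ref in self.reference_genes:
                    if (sid, ref) not in self._ct:
                        raise ValidationError(
                            f"sample {sid!r} lacks reference gene {ref!r}"
                        )

    # -- access ------------------------------------------------------------
    def ct(self, sample_id: str, gene: str) -> float | None:
        try:
            return self._ct[(sample_id, gene)]
        except KeyError:
            raise KeyError(f"no measurement for sample {sample_id!r}, gene {gene!r}") from None

    def has(self, sample_id: str, gene: str) -> bool:
        return (sample_id, gene) in self._ct

    def ref_mean(self, sample_id: str) -> float:
        """Mean reference-gene Ct in a sample (cached; error if any ref is
        undetermined, since the normalization anchor is then meaningless)."""
        cached = self._ref_mean.get(sample_id)
        if cached is not None:
            return cached
        total = 0.0
        for ref in self.reference_genes:
            ct = self.ct(sample_id, ref)
            if ct is None:
                raise ValidationError(
                    f"reference gene {ref!r} undetermined in sample {sample_id!r}"
                )
            total += ct
        mean = total / len(self.reference_genes)
        self._ref_mean[sample_id] = mean
        return mean

    @property
    def genes(self) -> list[str]:
        """All measured genes (reference genes included), sorted."""
        return sorted({m.gene for m in self.measurements})

    @property
    def target_genes(self) -> list[str]:
        refs = set(self.reference_genes)
        return [g for g in self.genes if g not in refs]

    @property
    def sample_ids(self) -> list[str]:
        return sorted({m.sample_id for m in self.measurements})


@dataclass
class RQRecord:
    """Per-gene relative-quantity summary across patients.

    ``per_patient_rq`` may be empty when the record was loaded from a
    precomputed median-RQ table rather than from raw Ct data; the median
    invariant is enforced only when per-patient values are present.
    """

    gene: str
    median_rq: float
    signed_fold: float
    per_patient_rq: dict[str, float] = field(default_factory=dict)
    n_informative_pairs: int = 0

    def __post_init__(self) -> None:
        if self.median_rq <= 0:
            raise ValidationError(f"{self.gene}: median_rq must be positive")
        if self.per_patient_rq:
            med = float(np.median(list(self.per_patient_rq.values())))
            if not math.isclose(med, self.median_rq, rel_tol=1e-9, abs_tol=1e-12):
                raise ValidationError(
                    f"{self.gene}: median_rq {self.median_rq} does not equal the "
                    f"median of per-patient RQs ({med})"
                )
        expected = signed_fold(self.median_rq)
        if not math.isclose(expected, self.signed_fold, rel_tol=1e-9, abs_tol=1e-12):
            raise ValidationError(
                f"{self.gene}: signed_fold {self.signed_fold} inconsistent with "
                f"median_rq {self.median_rq} (expected {expected})"
            )


def delta_ct(sample_id: str, gene: str, dataset: CtDataset) -> float | None:
    """dCt = Ct(gene) - mean Ct(reference genes), within one sample.

    Returns ``None`` when the target is undetermined (censored; the pairing
    step decides whether to impute).  An undetermined reference gene is a
    hard error because the normalization anchor is then meaningless.
    """
    ref_mean = dataset.ref_mean(sample_id)
    target = dataset.ct(sample_id, gene)
    if target is None:
        return None
    return target - ref_mean


def rq_for_pair(pair: PairedSample, gene: str, dataset: CtDataset) -> float | None:
    """RQ = 2^-(dCt_tumor - dCt_normal) for one patient, or ``None``.

    ``None`` marks the pair non-informative (gene undetermined in both
    members).  A single undetermined member is imputed at ``max_cycles``.
    """
    ct_t = dataset.ct(pair.tumor_sample_id, gene)
    ct_n = dataset.ct(pair.normal_sample_id, gene)
    if ct_t is None and ct_n is None:
        return None
    # censoring policy: a single undetermined member is imputed at max_cycles
    if ct_t is None:
        ct_t = dataset.max_cycles
    if ct_n is None:
        ct_n = dataset.max_cycles
    dct_t = ct_t - dataset.ref_mean(pair.tumor_sample_id)
    dct_n = ct_n - dataset.ref_mean(pair.normal_sample_id)
    return float(2.0 ** (-(dct_t - dct_n)))


def median_rq(gene: str, dataset: CtDataset) -> RQRecord:
    """Median RQ across informative pairs, with the signed-fold transform.

    For an even number of pairs the median is the midpoint of the two central
    values on the RQ scale (which differs from exponentiating the median
    ddCt; the odd-n case coincides).  Raises :class:`NotEvaluableError` when
    no pair is informative.
    """
    per_patient: dict[str, float] = {}
    for pair in dataset.pairs:
        rq = rq_for_pair(pair, gene, dataset)
        if rq is not None:
            per_patient[pair.patient_id] = rq
    if not per_patient:
        raise NotEvaluableError(f"gene {gene!r}: no informative tumor/normal pair")
    med = float(np.median(list(per_patient.values())))
    return RQRecord(
        gene=gene,
        median_rq=med,
        signed_fold=signed_fold(med),
        per_patient_rq=per_patient,
        n_informative_pairs=len(per_patient),
    )


def quantify(dataset: CtDataset) -> tuple[list[RQRecord], list[str]]:
    """Median RQ for every target gene.

    Returns ``(records, not_evaluable)`` where the second list names genes
    with zero informative pairs (excluded downstream).
    """
    records: list[RQRecord] = []
    dropped: list[str] = []
    for gene in dataset.target_genes:
        try:
            records.append(median_rq(gene, dataset))
        except NotEvaluableError:
            dropped.append(gene)
    return records, dropped


def signed_fold(rq: float) -> float:
    """Display transform: RQ for induction, -1/RQ for repression.

    Maps (0, inf) onto (-inf, -1] U [1, inf); the sign encodes direction and
    the magnitude is always a fold change >= 1.
    """
    rq = float(rq)
    if rq <= 0 or not math.isfinite(rq):
        raise ValidationError(f"rq must be a positive finite real, got {rq!r}")
    return rq if rq >= 1.0 else -1.0 / rq


def detection_rate(
    dataset: CtDataset, detect_threshold: float | None = None
) -> tuple[int, int, float]:
    """Panel QC: fraction of probes detected in at least one sample.

    A probe (gene) counts as detected if it has a determined Ct strictly
    below ``detect_threshold`` (default: ``max_cycles``) in any sample.
    Returns ``(n_detected, n_total, fraction)``.
    """
    if not dataset.measurements:
        raise ValidationError("empty dataset: no measurements")
    threshold = dataset.max_cycles if detect_threshold is None else float(detect_threshold)
    detected: set[str] = set()
    genes: set[str] = set()
    for m in dataset.measurements:
        genes.add(m.gene)
        if m.ct is not None and m.ct < threshold:
            detected.add(m.gene)
    n_total = len(genes)
    n_det = len(detected)
    return n_det, n_total, n_det / n_total
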