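"""Synthetic-data generation with recorded ground truth.

Emulates the inputs the pipeline consumes:

* paired tumor/normal Ct matrices from a low-density qPCR panel, with
  designated reference genes, spiked log2 fold changes, Gaussian technical
  noise on Ct, optional patient-level heterogeneity of the tumor effect, and
  detection-limit censoring (Ct beyond the last cycle is emitted as
  undetermined);
* gene annotation catalogs (localization, activity) for the simulated panel;
* somatic-mutation catalogs enriched in a chosen direction;
* xenograft trajectories with exponential growth, per-flank random
  intercepts, and lognormal measurement noise, emitted either as caliper
  (A, B) pairs (inverting V = 0.4 A B^2 at a fixed aspect ratio) or as a
  positive signal directly.

Every generator takes a seed (or rng) and returns the ground truth next to
the data, so recovery tests can compare estimates against what was planted.
The truth is never written into the data files the pipeline reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .catalog import Activity, DegradomeCatalog, Localization, ProteaseGene
from .enrichment import MutationCatalog
from .errors import ConfigurationError
from .quant import CtDataset, CtMeasurement, PairedSample
from .xenograft import Group, GrowthMeasurement, GrowthSeries

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "simulate_ct_experiment",
    "simulate_mutation_catalog",
    "simulate_xenograft",
    "catalog_from_truth",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped defaults for the paired qPCR simulation.

    The defaults mirror the discovery-cohort design: 14 tumor/normal pairs,
    a ~600-gene panel with two endogenous controls, half-cycle technical
    noise, 0.3-cycle patient-level heterogeneity of the tumor effect, and a
    40-cycle detection limit.  Spiked |log2 fold| magnitudes follow a shifted
    exponential (min + Exp(scale)) so some spikes straddle the 4-fold call
    threshold.
    """

    n_patients: int = 14
    n_genes: int = 600
    n_reference_genes: int = 2
    n_spike_up: int = 40
    n_spike_down: int = 60
    spike_lfc_min: float = 1.0
    spike_lfc_scale: float = 1.5
    ct_noise_sd: float = 0.5
    patient_effect_sd: float = 0.3
    baseline_dct_range: tuple[float, float] = (4.0, 12.0)
    reference_ct: float = 20.0
    censor_ct: float = 40.0
    fraction_extracellular: float = 0.5
    p_mut_down: float = 0.14
    p_mut_up: float = 0.04
    p_mut_background: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spike_up + self.n_spike_down > self.n_genes:
            raise ConfigurationError(
                f"spike counts ({self.n_spike_up}+{self.n_spike_down}) exceed "
                f"n_genes ({self.n_genes})"
            )
        for name in ("ct_noise_sd", "patient_effect_sd", "spike_lfc_min", "spike_lfc_scale"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        for name in ("fraction_extracellular", "p_mut_down", "p_mut_up", "p_mut_background"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be a probability, got {v}")
        if self.n_reference_genes < 1:
            raise ConfigurationError("need at least one reference gene")


@dataclass
class SimulatedTruth:
    """Ground truth recorded alongside the emitted data."""

    lfc: dict[str, float]  # per-gene true log2 fold change (tumor vs normal)
    direction: dict[str, str]  # "up" / "down" / "null"
    localization: dict[str, Localization]
    mutated: frozenset[str] = frozenset()
    xenograft_slopes: dict[str, float] = field(default_factory=dict)

    @property
    def up_genes(self) -> list[str]:
        return [g for g, d in self.direction.items() if d == "up"]

    @property
    def down_genes(self) -> list[str]:
        return [g for g, d in self.direction.items() if d == "down"]


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def simulate_ct_experiment(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[CtDataset, SimulatedTruth]:
    """Paired tumor/normal Ct matrix with spiked fold changes.

    Model per gene g and patient p: the normal-sample dCt_g is drawn once
    per gene from ``baseline_dct_range``; the tumor dCt is
    dCt_g - lfc_g + N(0, patient_effect_sd); emitted Ct values add the
    reference level and N(0, ct_noise_sd).  Reference genes carry noise
    only.  Any Ct above ``censor_ct`` is emitted as undetermined.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    genes = _gene_names(config.n_genes)
    refs = [f"REF{i}" for i in range(1, config.n_reference_genes + 1)]

    order = rng.permutation(config.n_genes)
    up_idx = order[: config.n_spike_up]
    down_idx = order[config.n_spike_up : config.n_spike_up + config.n_spike_down]
    lfc = np.zeros(config.n_genes)
    lfc[up_idx] = config.spike_lfc_min + rng.exponential(
        config.spike_lfc_scale, size=len(up_idx)
    )
    lfc[down_idx] = -(
        config.spike_lfc_min + rng.exponential(config.spike_lfc_scale, size=len(down_idx))
    )
    direction = np.full(config.n_genes, "null", dtype=object)
    direction[up_idx] = "up"
    direction[down_idx] = "down"

    lo, hi = config.baseline_dct_range
    base_dct = rng.uniform(lo, hi, size=config.n_genes)

    loc_draw = rng.random(config.n_genes)
    sub_draw = rng.random(config.n_genes)
    localization = [
        (Localization.EC_S if s < 0.5 else Localization.EC_TM)
        if l < config.fraction_extracellular
        else Localization.IC
        for l, s in zip(loc_draw, sub_draw)
    ]

    measurements: list[CtMeasurement] = []
    pairs: list[PairedSample] = []
    n_p, n_g = config.n_patients, config.n_genes
    noise = rng.normal(0.0, config.ct_noise_sd, size=(n_p, 2, n_g)) if config.ct_noise_sd > 0 else np.zeros((n_p, 2, n_g))
    ref_noise = rng.normal(0.0, config.ct_noise_sd, size=(n_p, 2, len(refs))) if config.ct_noise_sd > 0 else np.zeros((n_p, 2, len(refs)))
    tumor_het = (
        rng.normal(0.0, config.patient_effect_sd, size=(n_p, n_g))
        if config.patient_effect_sd > 0
        else np.zeros((n_p, n_g))
    )

    for p in range(n_p):
        pid = f"P{p + 1:02d}"
        sid_t, sid_n = f"{pid}T", f"{pid}N"
        pairs.append(PairedSample(pid, sid_t, sid_n))
        ct_n = base_dct + config.reference_ct + noise[p, 0]
        ct_t = base_dct - lfc + tumor_het[p] + config.reference_ct + noise[p, 1]
        for tissue_idx, (sid, cts) in enumerate(((sid_n, ct_n), (sid_t, ct_t))):
            for g in range(n_g):
                ct = float(cts[g])
                measurements.append(
                    CtMeasurement(sid, genes[g], None if ct > config.censor_ct else ct)
                )
            for r, ref in enumerate(refs):
                measurements.append(
                    CtMeasurement(
                        sid, ref, float(config.reference_ct + ref_noise[p, tissue_idx, r])
                    )
                )

    dataset = CtDataset(
        measurements, pairs, reference_genes=refs, max_cycles=config.censor_ct
    )
    truth = SimulatedTruth(
        lfc=dict(zip(genes, (float(v) for v in lfc))),
        direction=dict(zip(genes, (str(d) for d in direction))),
        localization=dict(zip(genes, localization)),
    )
    return dataset, truth


def catalog_from_truth(truth: SimulatedTruth) -> DegradomeCatalog:
    """Annotation catalog for a simulated panel.

    All simulated genes are proteases; the array background equals the
    panel's own compartment composition (the simulated panel is the whole
    universe).
    """
    entries = tuple(
        ProteaseGene(symbol=g, localization=loc, activity=Activity.PROTEASE)
        for g, loc in truth.localization.items()
    )
    n_ec = sum(
        1 for loc in truth.localization.values()
        if loc in (Localization.EC_S, Localization.EC_TM)
    )
    n_ic = len(entries) - n_ec
    return DegradomeCatalog(entries=entries, array_background=(n_ec, n_ic))


def simulate_mutation_catalog(
    truth: SimulatedTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    name: str = "simulated",
) -> MutationCatalog:
    """Mutation catalog with direction-dependent inclusion probabilities.

    Each true-down gene enters with probability ``p_mut_down``, each true-up
    gene with ``p_mut_up``, and every other gene with ``p_mut_background``.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    prob = {"down": config.p_mut_down, "up": config.p_mut_up, "null": config.p_mut_background}
    members = [
        g for g, d in truth.direction.items() if rng.random() < prob[d]
    ]
    return MutationCatalog(name=name, symbols=frozenset(members))


def simulate_xenograft(
    n_flanks: int = 8,
    days: Sequence[float] = (0.0, 7.0, 14.0, 21.0, 28.0),
    slope_control: float = 0.15,
    slope_treated: float = 0.05,
    intercept: float = 4.0,
    flank_sd: float = 0.3,
    noise_sd: float = 0.15,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    output: str = "volume",
    aspect_ratio: float = 2.0,
) -> GrowthSeries:
    """Exponential xenograft growth with per-flank random intercepts.

    log volume = intercept + flank effect + slope * day + N(0, noise_sd),
    per group slope.  ``output="volume"`` emits caliper (A, B) pairs by
    inverting V = 0.4 A B^2 at the fixed aspect ratio A = aspect * B;
    ``output="signal"`` emits the exponentiated response directly (photon
    flux).  The configured slopes and sds are the recoverable ground truth.
    """
    if n_flanks < 2:
        raise ConfigurationError("need at least 2 flanks per group")
    if noise_sd < 0 or flank_sd < 0:
        raise ConfigurationError("noise and flank sds must be nonnegative")
    if aspect_ratio < 1.0:
        raise ConfigurationError("aspect_ratio must be >= 1 so that A >= B")
    if output not in ("volume", "signal"):
        raise ConfigurationError(f"unknown output kind {output!r}")
    rng = np.random.default_rng(seed) if rng is None else rng
    slopes = {Group.CONTROL: slope_control, Group.TREATED: slope_treated}
    measurements: list[GrowthMeasurement] = []
    for group in (Group.CONTROL, Group.TREATED):
        for f in range(n_flanks):
            fid = f"{group.value[:3]}{f + 1:02d}"
            u = rng.normal(0.0, flank_sd) if flank_sd > 0 else 0.0
            for day in days:
                eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                log_v = intercept + u + slopes[group] * day + eps
                value = float(np.exp(log_v))
                if output == "signal":
                    measurements.append(
                        GrowthMeasurement(fid, group, float(day), signal=value)
                    )
                else:
                    B = (value / (0.4 * aspect_ratio)) ** (1.0 / 3.0)
                    measurements.append(
                        GrowthMeasurement(
                            fid, group, float(day), A=aspect_ratio * B, B=B
                        )
                    )
    return GrowthSeries(measurements)
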