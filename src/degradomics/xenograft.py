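"""Xenograft and proliferation growth-curve analysis.

Tumor burden trajectories (caliper volumes, photon flux, or MTT absorbance)
are compared between a control and a treated group with a linear
mixed-effects model on a log-scale response:

    y_ij = b0 + b1 * day_ij + b2 * group_i + b3 * (group_i * day_ij)
           + u_i + e_ij,   u_i ~ N(0, s_b^2),  e_ij ~ N(0, s_e^2)

with a random intercept per flank (the unit of analysis; each mouse
contributes two flanks).  The model is fitted by maximum likelihood,
profiling the likelihood over the variance ratio s_b^2/s_e^2, and the group
effect is assessed by a likelihood-ratio test of the group and group x day
terms against the nested no-group model (chi-square, 2 df).  A permutation
fallback re-randomizes flank-to-group assignments and uses the same LRT
statistic, which frees the p-value from the chi-square approximation at
small flank counts.

Volumes from caliper measurements use V = 0.4 * A * B^2 with A the largest
and B the smallest tumor dimension.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .errors import ConfigurationError, ValidationError

__all__ = [
    "Group",
    "GrowthMeasurement",
    "GrowthSeries",
    "GrowthFit",
    "tumor_volume",
    "normalize_to_baseline",
    "summarize_groups",
    "growth_curve_compare",
]


class Group(str, enum.Enum):
    CONTROL = "control"
    TREATED = "treated"


def tumor_volume(A: float, B: float) -> float:
    """Caliper volume V = 0.4 * A * B^2 (mm^3); A >= B > 0."""
    A, B = float(A), float(B)
    if A <= 0 or B <= 0:
        raise ValidationError(f"dimensions must be positive, got A={A}, B={B}")
    if A < B:
        raise ValidationError(
            f"A must be the largest dimension (A={A} < B={B}); swap the calipers"
        )
    return 0.4 * A * B * B


@dataclass(frozen=True)
class GrowthMeasurement:
    """One reading on one flank: either a caliper (A, B) pair or a signal.

    ``signal`` covers photon flux and absorbance; exactly one of the two
    measurement kinds must be populated.
    """

    flank_id: str
    group: Group
    day: float
    A: float | None = None
    B: float | None = None
    signal: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", Group(self.group))
        if self.day < 0:
            raise ValidationError(f"day must be nonnegative, got {self.day}")
        has_caliper = self.A is not None or self.B is not None
        has_signal = self.signal is not None
        if has_caliper == has_signal:
            raise ValidationError(
                f"{self.flank_id} day {self.day}: exactly one of (A, B) or signal "
                "must be populated"
            )
        if has_caliper:
            if self.A is None or self.B is None:
                raise ValidationError(
                    f"{self.flank_id} day {self.day}: both A and B are required"
                )
            tumor_volume(self.A, self.B)  # validates A >= B > 0
        elif self.signal is not None and self.signal <= 0:
            raise ValidationError(
                f"{self.flank_id} day {self.day}: signal must be positive"
            )

    @property
    def value(self) -> float:
        """The response: caliper volume or the raw signal."""
        if self.signal is not None:
            return self.signal
        return tumor_volume(self.A, self.B)


class GrowthSeries:
    """Longitudinal measurements grouped by flank with a group design."""

    def __init__(self, measurements: Iterable[GrowthMeasurement]):
        self.measurements = tuple(measurements)
        if not self.measurements:
            raise ValidationError("empty growth series")
        design: dict[str, Group] = {}
        days: dict[str, list[float]] = {}
        for m in self.measurements:
            if m.flank_id in design and design[m.flank_id] != m.group:
                raise ValidationError(
                    f"flank {m.flank_id!r} assigned to more than one group"
                )
            design[m.flank_id] = m.group
            days.setdefault(m.flank_id, []).append(m.day)
        for fid, ds in days.items():
            if any(b <= a for a, b in zip(ds, ds[1:])):
                raise ValidationError(
                    f"flank {fid!r}: days must be strictly increasing"
                )
        self.design = design

    def n_flanks(self, group: Group | str) -> int:
        group = Group(group)
        return sum(1 for g in self.design.values() if g is group)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "flank_id": [m.flank_id for m in self.measurements],
                "group": [m.group.value for m in self.measurements],
                "day": [m.day for m in self.measurements],
                "value": [m.value for m in self.measurements],
            }
        )


def normalize_to_baseline(
    series: Sequence[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Divide every value by the value at the earliest time point.

    The first ratio is exactly 1; a missing or nonpositive baseline is an
    error because ratios would be meaningless.
    """
    if not series:
        raise ValidationError("empty series")
    ordered = sorted(series, key=lambda tv: tv[0])
    baseline = ordered[0][1]
    if baseline is None or baseline <= 0:
        raise ValidationError(f"baseline value at t={ordered[0][0]} must be positive")
    return [(t, v / baseline) for t, v in ordered]


def summarize_groups(series: GrowthSeries) -> pd.DataFrame:
    """Per-(group, day) mean and SEM of the response.

    SEM = sd / sqrt(n) with the n-1 denominator in sd; a single observation
    leaves SEM missing (NaN).
    """
    df = series.to_frame()
    out = (
        df.groupby(["group", "day"])["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out[["group", "day", "mean", "sem", "n"]]


# ---------------------------------------------------------------------------
# random-intercept LMM by profile maximum likelihood
# ---------------------------------------------------------------------------

_TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "log1p": np.log1p,
    "log": np.log,
    "identity": lambda y: y,
}


class _ProfileLMM:
    """ML fit of y = X beta + u_flank + e via the profiled variance ratio.

    With lam = s_b^2 / s_e^2 the marginal covariance is block diagonal,
    V_i = s_e^2 (I + lam J) per flank, so GLS cross-products reduce to
    per-flank sums (Woodbury): V_i^{-1} = I - lam/(1 + lam n_i) J.  The
    profile log-likelihood is maximized over log(lam) by scalar search,
    with the lam = 0 (OLS) boundary checked explicitly.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, flanks: np.ndarray):
        self.y = y
        self.X = X
        self.N, self.p = X.shape
        # per-flank sufficient statistics, stacked so each lambda evaluation
        # is a handful of vectorized ops rather than a Python loop
        uniq, inv = np.unique(flanks, return_inverse=True)
        F = len(uniq)
        self.n_g = np.bincount(inv).astype(float)  # (F,)
        self.sx = np.zeros((F, self.p))  # per-flank column sums of X
        np.add.at(self.sx, inv, X)
        self.sy = np.bincount(inv, weights=y)  # (F,)
        self.S_XtX = X.T @ X
        self.S_Xty = X.T @ y
        self.S_yty = float(y @ y)

    def _gls(self, lam: float):
        c = lam / (1.0 + lam * self.n_g)  # (F,)
        XtVX = self.S_XtX - (self.sx * c[:, None]).T @ self.sx
        XtVy = self.S_Xty - self.sx.T @ (c * self.sy)
        ytVy = self.S_yty - float(c @ (self.sy**2))
        logdet = float(np.sum(np.log1p(lam * self.n_g)))
        beta = np.linalg.solve(XtVX, XtVy)
        rss = ytVy - 2.0 * beta @ XtVy + beta @ XtVX @ beta
        rss = max(rss, 1e-300)
        return beta, rss, logdet, XtVX

    def loglik(self, lam: float) -> float:
        _, rss, logdet, _ = self._gls(lam)
        sigma2 = rss / self.N
        return -0.5 * (self.N * (math.log(2 * math.pi * sigma2) + 1.0) + logdet)

    def fit(self):
        res = minimize_scalar(
            lambda t: -self.loglik(math.exp(t)),
            bounds=(-12.0, 12.0),
            method="bounded",
            options={"xatol": 1e-8},
        )
        candidates = [(self.loglik(0.0), 0.0)]
        if res.success or math.isfinite(res.fun):
            lam = math.exp(float(res.x))
            candidates.append((-float(res.fun), lam))
        ll, lam = max(candidates, key=lambda c: c[0])
        beta, rss, _, XtVX = self._gls(lam)
        sigma2_e = rss / self.N
        cov_beta = sigma2_e * np.linalg.inv(XtVX)
        return {
            "loglik": ll,
            "lambda": lam,
            "beta": beta,
            "sigma2_e": sigma2_e,
            "sigma2_b": lam * sigma2_e,
            "se_beta": np.sqrt(np.diag(cov_beta)),
        }


@dataclass(frozen=True)
class GrowthFit:
    """Fitted group comparison.

    ``fixed_effects`` holds intercept, day slope, group offset and the
    group x day interaction (the growth-rate difference on the transformed
    scale); ``statistic`` is the 2-df likelihood-ratio statistic for the two
    group terms.
    """

    fixed_effects: dict[str, float]
    fixed_effects_se: dict[str, float]
    sigma2_flank: float
    sigma2_resid: float
    statistic: float
    p_value: float
    method: str
    n_perm: int | None = None
    transform: str = "log1p"

    def __post_init__(self) -> None:
        if self.sigma2_flank < 0 or self.sigma2_resid < 0:
            raise ValidationError("variance components must be nonnegative")
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"p_value must lie in (0, 1], got {self.p_value}")


_EFFECT_NAMES = ("intercept", "day", "group", "group_x_day")


def _design(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    day = df["day"].to_numpy(dtype=float)
    grp = (df["group"] == Group.TREATED.value).to_numpy(dtype=float)
    X_alt = np.column_stack([np.ones_like(day), day, grp, grp * day])
    X_null = X_alt[:, :2]
    return X_alt, X_null, day, grp


def _lrt(y, X_alt, X_null, flanks) -> tuple[float, dict]:
    alt = _ProfileLMM(y, X_alt, flanks).fit()
    null = _ProfileLMM(y, X_null, flanks).fit()
    stat = max(0.0, 2.0 * (alt["loglik"] - null["loglik"]))
    return stat, alt


def growth_curve_compare(
    series: GrowthSeries,
    transform: str = "log1p",
    method: str = "lmm",
    n_perm: int = 999,
    seed: int | None = None,
) -> GrowthFit:
    """Compare control vs treated growth curves.

    Parameters
    ----------
    transform
        Response transform: ``log1p`` (volumes; tolerates zeros), ``log``
        (photon flux / normalized ratios) or ``identity``.
    method
        ``"lmm"``: likelihood-ratio test of the group and group x day fixed
        effects against a chi-square with 2 df.  ``"permutation"``: the same
        statistic, calibrated by ``n_perm`` random reassignments of flanks to
        groups, p = (1 + #{perm >= obs}) / (1 + n_perm).
    """
    if transform not in _TRANSFORMS:
        raise ConfigurationError(f"unknown transform {transform!r}")
    if method not in ("lmm", "permutation"):
        raise ConfigurationError(f"unknown method {method!r}")
    df = series.to_frame()
    groups_present = sorted(df["group"].unique())
    if len(groups_present) < 2:
        raise ValidationError("need both a control and a treated group")
    if df["day"].nunique() < 3:
        raise ValidationError("need measurements at >= 3 time points")
    for g in groups_present:
        if series.n_flanks(g) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 flanks")

    y = _TRANSFORMS[transform](df["value"].to_numpy(dtype=float))
    if not np.all(np.isfinite(y)):
        raise ValidationError(
            f"transform {transform!r} produced non-finite responses"
        )
    flanks = df["flank_id"].to_numpy()
    X_alt, X_null, day, _ = _design(df)
    stat, alt = _lrt(y, X_alt, X_null, flanks)

    if method == "lmm":
        p = float(chi2.sf(stat, df=2)) if stat > 0 else 1.0
        method_label = "lmm_lrt"
        n_perm_used = None
    else:
        rng = np.random.default_rng(seed)
        flank_ids = np.array(sorted(series.design))
        flank_groups = np.array([series.design[f].value for f in flank_ids])
        ones = np.ones_like(day)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(flank_groups)
            lut = dict(zip(flank_ids, perm))
            grp_perm = np.array(
                [1.0 if lut[f] == Group.TREATED.value else 0.0 for f in flanks]
            )
            Xp = np.column_stack([ones, day, grp_perm, grp_perm * day])
            stat_p, _ = _lrt(y, Xp, X_null, flanks)
            if stat_p >= stat:
                exceed += 1
        p = (1.0 + exceed) / (1.0 + n_perm)
        method_label = "permutation"
        n_perm_used = n_perm

    return GrowthFit(
        fixed_effects=dict(zip(_EFFECT_NAMES, (float(b) for b in alt["beta"]))),
        fixed_effects_se=dict(zip(_EFFECT_NAMES, (float(s) for s in alt["se_beta"]))),
        sigma2_flank=float(alt["sigma2_b"]),
        sigma2_resid=float(alt["sigma2_e"]),
        statistic=float(stat),
        p_value=min(1.0, max(p, 5e-324)),
        method=method_label,
        n_perm=n_perm_used,
        transform=transform,
    )
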