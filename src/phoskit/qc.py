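"""Quality control and sensitivity machinery.

Three concerns live here: (1) detection-limit statistics — per-sample
t-scores across the light levels, the Student-t critical value, and the
power-law fit of t vs chlorophyll that yields the minimum usable Chla;
(2) the PAR self-shading model that caps culture optical density; and
(3) the perturbation sensitivity analysis that propagates plausible
alkalinity and pH calibration errors through the whole rate pipeline to the
fitted P-vs-E parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from . import carbonate as cb
from .errors import (
    DomainError,
    ExtrapolationWarning,
    InsufficientDataError,
    UndefinedStatisticError,
)
from .photophys import PvEFit, fit_platt_offset
from .trace import OscillationTrace, pve_points

__all__ = [
    "DetectionProfile",
    "SensitivityReport",
    "t_score",
    "mean_abs_t",
    "detection_t",
    "critical_t",
    "detection_limit",
    "attenuation_fraction",
    "fit_attenuation",
    "max_od_for_loss",
    "default_perturbations",
    "sensitivity_table",
]


def t_score(sample_values) -> np.ndarray:
    """Per-sample t-scores within one replicate set.

    t_i = (x_i - xbar) / (s / sqrt(n)): each sample's deviation from the mean
    in units of the standard error of the mean. Raises if the sample has zero
    variance (t undefined).
    """
    x = np.asarray(sample_values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("t-score needs at least 2 samples")
    s = x.std(ddof=1)
    if s == 0.0:
        raise UndefinedStatisticError("zero sample variance; t-score undefined")
    return (x - x.mean()) / (s / np.sqrt(x.size))


def mean_abs_t(per_level_samples: Sequence[Sequence[float]]) -> float:
    """Mean |t| across light levels for one Chla concentration.

    Each inner sequence holds the replicate rates at one light level; the
    aggregate is the mean of the per-level |t| values.
    """
    vals = [np.abs(t_score(level)).mean() for level in per_level_samples]
    return float(np.mean(vals))


def detection_t(replicate_rates) -> float:
    """Replicate-disagreement t for one Chla concentration.

    ``replicate_rates`` has shape (replicates, light levels). Each individual
    measurement error x - xbar (deviation from the replicate mean at its
    light level) is divided by the standard error of the mean of the samples
    across the light levels, s/sqrt(n) with n the number of light levels
    (hence df = n - 1 = 6 for the seven-step protocol); the reported score is
    the mean |t|. Because the SEM is set by the P-vs-E signal spread while
    the deviations are instrument noise, the score falls as chlorophyll (and
    with it signal) increases and rises with instrument noise.
    """
    r = np.asarray(replicate_rates, dtype=float)
    if r.ndim != 2 or r.shape[0] < 2:
        raise InsufficientDataError("need >= 2 replicates x >= 2 light levels")
    level_mean = r.mean(axis=0)
    dev = r - level_mean
    n_levels = r.shape[1]
    s = level_mean.std(ddof=1)
    if s == 0.0:
        raise UndefinedStatisticError("flat P-vs-E signal; t undefined")
    sem = s / np.sqrt(n_levels)
    return float(np.mean(np.abs(dev)) / sem)


def critical_t(df: int, one_tailed_confidence: float = 0.95) -> float:
    """One-tailed Student-t critical value (1.943 at df=6, 95%)."""
    if df < 1:
        raise DomainError("df must be >= 1")
    return float(stats.t.ppf(one_tailed_confidence, df))


@dataclass(frozen=True)
class DetectionProfile:
    """Power-law fit of t-score vs Chla and the implied detection limit.

    t(chla) = c * chla**(-k); ``min_chla`` solves t = critical_value.
    ``extrapolated`` marks a crossing outside the fitted data range.
    """

    chla: np.ndarray
    t: np.ndarray
    c: float
    k: float
    critical_value: float
    min_chla: float
    extrapolated: bool


def detection_limit(profiles, cv: float) -> DetectionProfile:
    """Minimum usable Chla from t-vs-Chla points.

    ``profiles`` is a sequence of (chla, t) pairs (>= 3 levels). A power
    function is fitted by least squares in log-log space and intersected with
    the critical value; if the crossing falls outside the observed chla range
    an extrapolation warning is raised but the value is still returned.
    """
    arr = np.asarray(profiles, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise InsufficientDataError("need >= 3 (chla, t) levels")
    chla, t = arr[:, 0], arr[:, 1]
    if np.any(chla <= 0) or np.any(t <= 0):
        raise DomainError("chla and t must be positive for a power-law fit")
    slope, intercept = np.polyfit(np.log(chla), np.log(t), 1)
    c, k = float(np.exp(intercept)), float(-slope)
    if k <= 0:
        raise DomainError("t does not decrease with chla; no detection limit")
    min_chla = (c / cv) ** (1.0 / k)
    extrapolated = not (chla.min() <= min_chla <= chla.max())
    if extrapolated:
        warnings.warn(
            f"critical value {cv} not crossed within the data range; "
            f"extrapolated min_chla = {min_chla:.3g}",
            category=ExtrapolationWarning,
            stacklevel=2,
        )
    return DetectionProfile(
        chla=chla, t=t, c=c, k=k, critical_value=float(cv),
        min_chla=float(min_chla), extrapolated=extrapolated,
    )


def attenuation_fraction(od750: float, a: float, b: float) -> float:
    """Fractional PAR loss at the cuvette center: exp(a * OD750 - b).

    The loss is reported as a positive fraction in (0, 1); the empirical
    coefficients a, b come from :func:`fit_attenuation`.
    """
    if od750 < 0:
        raise DomainError("od750 must be non-negative")
    return float(np.exp(a * od750 - b))


def fit_attenuation(od_values, measured_loss) -> tuple[float, float, float]:
    """Least-squares fit of log(loss) = a * OD750 - b.

    Returns (a, b, r^2). Requires >= 3 points with positive losses.
    """
    od = np.asarray(od_values, dtype=float)
    loss = np.asarray(measured_loss, dtype=float)
    if od.size < 3:
        raise InsufficientDataError("need >= 3 attenuation points")
    if np.any(loss <= 0):
        raise DomainError("losses must be positive to fit in log space")
    fit = stats.linregress(od, np.log(loss))
    return float(fit.slope), float(-fit.intercept), float(fit.rvalue**2)


def max_od_for_loss(a: float, b: float, max_loss: float) -> float:
    """OD750 ceiling for a tolerated fractional PAR loss:
    od = (b + ln(max_loss)) / a."""
    if not 0.0 < max_loss < 1.0:
        raise DomainError("max_loss must be in (0, 1)")
    return (b + np.log(max_loss)) / a


@dataclass
class SensitivityReport:
    """Percent changes of fitted P-vs-E parameters under input perturbations."""

    baseline: PvEFit
    rows: list[dict]

    def as_table(self) -> str:
        lines = [f"{'perturbation':<14}{'dP_max %':>10}{'dalpha %':>10}{'dbeta %':>10}"]
        for r in self.rows:
            beta = "0" if np.isnan(r["dbeta_pct"]) else f"{r['dbeta_pct']:+.2f}"
            lines.append(
                f"{r['label']:<14}{r['dP_max_pct']:>+10.2f}{r['dalpha_pct']:>+10.2f}"
                f"{beta:>10}"
            )
        return "\n".join(lines)


def default_perturbations() -> list[tuple[str, str, float]]:
    """The standard error families: alkalinity +-1%, pH calibration +-0.01."""
    return [
        ("A_T +1%", "A_T", +0.01),
        ("A_T -1%", "A_T", -0.01),
        ("pH +0.01", "pH", +0.01),
        ("pH -0.01", "pH", -0.01),
    ]


def _perturbed_trace(
    trace: OscillationTrace, family: str, amount: float
) -> OscillationTrace:
    chem = trace.chemistry
    if family == "pH":
        out = dc_replace(trace)
        out.ph = trace.ph + amount
        return out
    if family == "A_T":
        new_chem = cb.MediumChemistry(
            chem.salinity,
            chem.temperature,
            chem.total_alkalinity * (1.0 + amount),
            chem.density,
            chem.total_borate,
            chem.total_phosphate,
            chem.total_silicate,
        )
        out = dc_replace(trace)
        out.chemistry = new_chem
        return out
    raise DomainError(f"unknown perturbation family {family!r}")


def sensitivity_table(
    trace: OscillationTrace,
    perturbations: Sequence[tuple[str, str, float]] | None = None,
    schedule=None,
    trim_s: float = 10.0,
) -> SensitivityReport:
    """Propagate alkalinity/pH-calibration errors to the fitted parameters.

    Reruns the full carbon pipeline (pH -> DIC -> per-step rates ->
    respiration-offset photoinhibition fit) once per perturbation and reports
    percent changes of P_max, alpha and beta against the unperturbed
    baseline. A uniform pH offset rescales all rates almost multiplicatively,
    so its P_max and alpha sensitivities agree closely.
    """
    if perturbations is None:
        perturbations = default_perturbations()

    def run(tr: OscillationTrace) -> PvEFit:
        pts = pve_points(tr, o2_cal=None, schedule=schedule, trim_s=trim_s)
        return fit_platt_offset(pts)

    base = run(trace)
    rows = []
    for label, family, amount in perturbations:
        fit = run(_perturbed_trace(trace, family, amount))
        dbeta = (
            100.0 * (fit.beta - base.beta) / base.beta
            if base.beta != 0.0
            else (0.0 if fit.beta == 0.0 else np.nan)
        )
        rows.append(
            {
                "label": label,
                "dP_max_pct": 100.0 * (fit.P_max / base.P_max - 1.0),
                "dalpha_pct": 100.0 * (fit.alpha / base.alpha - 1.0),
                "dbeta_pct": dbeta,
                "fit": fit,
            }
        )
    return SensitivityReport(baseline=base, rows=rows)
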