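"""Photophysiology: P-vs-E curve fitting, spectral absorption, absorbed-quanta
integration, quantum-yield series and the growth-based carbon-uptake check.

The central model is the photoinhibition-capable saturation curve

    P(I) = P_max (1 - exp(-alpha I / P_max)) exp(-beta I / P_max)

fitted to net rates after offsetting by the dark respiration so the curve
starts at zero (the function cannot take negative values), then shifting the
fitted curve back down by the same offset. The light-limited initial slope is
alternatively estimated with the hyperbolic-tangent form P = P_m tanh(alpha
I / P_m).

Quantum yield divides the chlorophyll-specific net rate by the absorbed
photon flux, the spectral integral of the chlorophyll-specific absorption
coefficient a*_ph(lambda) times the irradiance spectrum E_0(lambda) over
400-700 nm. Because net photosynthesis carries the respiration load, the
maximum yield sits at the peak of the Phi-vs-E curve at intermediate light,
not in the low-light limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import (
    DomainError,
    FitError,
    InsufficientDataError,
    SanityFlagWarning,
)
from .trace import SegmentRate

__all__ = [
    "PvEFit",
    "Spectrum",
    "PhiSeries",
    "platt",
    "fit_platt_offset",
    "tanh_initial_slope",
    "specific_absorption",
    "absorbed_quanta",
    "quantum_yield",
    "phi_series",
    "growth_pchl",
    "cn_ratio",
    "white_led_spectrum",
]

#: Physical ceiling on the quantum yield of O2 (1 O2 per 8 quanta); used as a
#: sanity bound for both gases.
PHI_CEILING = 0.125


def platt(I, p_max: float, alpha: float, beta: float = 0.0):
    """Photosynthesis vs irradiance with optional photoinhibition."""
    I = np.asarray(I, dtype=float)
    if p_max == 0.0:
        return np.zeros_like(I)
    return p_max * (1.0 - np.exp(-alpha * I / p_max)) * np.exp(-beta * I / p_max)


@dataclass
class PvEFit:
    """Fitted photosynthesis-irradiance curve for one gas.

    ``P_max``, ``alpha``, ``beta`` parameterize the offset (respiration-free)
    curve; ``respiration_offset`` R is the magnitude of the dark rate that was
    added before fitting. ``predict`` returns the net curve (offset curve
    minus R), which is what the measured rates follow.
    """

    points: list[SegmentRate] | None
    light: np.ndarray
    rates: np.ndarray
    P_max: float
    alpha: float
    beta: float
    respiration_offset: float
    se: dict[str, float]
    gas: str = "carbon"
    model: str = "platt"

    def predict(self, I):
        """Net photosynthetic rate at irradiance I (same units as rates)."""
        if self.model == "tanh":
            curve = self.P_max * np.tanh(self.alpha * np.asarray(I, float) / self.P_max)
        else:
            curve = platt(I, self.P_max, self.alpha, self.beta)
        return curve - self.respiration_offset


def _rates_and_offset(points) -> tuple[np.ndarray, np.ndarray, float]:
    if len(points) and isinstance(points[0], SegmentRate):
        light = np.array([p.light_level for p in points], dtype=float)
        rates = np.array([p.rate_DIC for p in points], dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        light, rates = arr[:, 0], arr[:, 1]
    order = np.argsort(light)
    light, rates = light[order], rates[order]
    dark = light == 0.0
    if not dark.any():
        raise InsufficientDataError("need a light=0 (dark respiration) point")
    R = float(abs(rates[dark][0]))
    return light, rates + R, R


def _multistart_fit(f, light, y, p0s, bounds):
    best = None
    for p0 in p0s:
        try:
            popt, pcov = optimize.curve_fit(
                f, light, y, p0=p0, bounds=bounds, maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        resid = float(np.sum((f(light, *popt) - y) ** 2))
        if best is None or resid < best[2]:
            best = (popt, pcov, resid)
    if best is None:
        raise FitError("P-vs-E fit failed to converge from all starts")
    return best[0], best[1]


def _starts(light, y, n_extra=5, seed=1234):
    pos = light > 0
    p_max0 = max(float(np.max(y[pos])), 1e-6)
    il, yl = light[pos][:2], y[pos][:2]
    alpha0 = max(float(yl[-1] / il[-1]), 1e-6) if len(il) else 1.0
    if len(il) == 2 and il[0] > 0:
        alpha0 = max(float(np.polyfit(np.r_[0, il], np.r_[0, yl], 1)[0]), 1e-6)
    rng = np.random.default_rng(seed)
    starts = [(p_max0, alpha0)]
    starts += [
        (p_max0 * rng.uniform(0.5, 2.0), alpha0 * rng.uniform(0.5, 2.0))
        for _ in range(n_extra)
    ]
    return starts


def fit_platt_offset(
    points, gas: str = "carbon", rate_attr: str | None = None
) -> PvEFit:
    """Fit the photoinhibition curve to P-vs-E points with respiration offset.

    ``points`` is a list of :class:`~phoskit.trace.SegmentRate` (the carbon
    rates are used unless ``rate_attr='rate_O2'``) or an (I, P) array. The
    dark rate sets the offset R; all rates are shifted up by R, the curve is
    fitted, and R is subtracted back out of predictions. A negative fitted
    photoinhibition parameter is clamped by refitting with beta fixed at 0.
    """
    is_seg = len(points) and isinstance(points[0], SegmentRate)
    if rate_attr == "rate_O2" and is_seg:
        pts = [(p.light_level, p.rate_O2) for p in points]
        light, y, R = _rates_and_offset(np.asarray(pts))
        seg_points = list(points)
    else:
        seg_points = list(points) if is_seg else None
        light, y, R = _rates_and_offset(points)
    if len(light) < 5:
        raise InsufficientDataError("need >= 5 points including light=0")

    starts3 = [(p, a, 0.0) for p, a in _starts(light, y)]
    popt, pcov = _multistart_fit(
        platt, light, y, starts3,
        bounds=([1e-9, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
    )
    if popt[2] < 0.0:
        def platt_b0(I, p_max, alpha):
            return platt(I, p_max, alpha, 0.0)

        popt2, pcov2 = _multistart_fit(
            platt_b0, light, y, _starts(light, y),
            bounds=([1e-9, 1e-9], [np.inf, np.inf]),
        )
        popt = np.array([popt2[0], popt2[1], 0.0])
        perr = np.r_[np.sqrt(np.diag(pcov2)), np.nan]
    else:
        perr = np.sqrt(np.diag(pcov))
    return PvEFit(
        points=seg_points,
        light=light,
        rates=y - R,
        P_max=float(popt[0]),
        alpha=float(popt[1]),
        beta=float(popt[2]),
        respiration_offset=R,
        se={"P_max": float(perr[0]), "alpha": float(perr[1]), "beta": float(perr[2])},
        gas=gas,
        model="platt",
    )


def tanh_initial_slope(points, gas: str = "carbon", rate_attr: str | None = None) -> float:
    """Light-limited initial slope from the hyperbolic-tangent P-vs-E form.

    Applies the same respiration-offset procedure, fits
    P = P_m tanh(alpha I / P_m), and returns alpha — which is exactly the
    fitted curve's derivative at I = 0.
    """
    if rate_attr == "rate_O2" and len(points) and isinstance(points[0], SegmentRate):
        points = np.asarray([(p.light_level, p.rate_O2) for p in points])
    light, y, _R = _rates_and_offset(points)
    if (light > 0).sum() < 3:
        raise InsufficientDataError("need >= 3 positive-light points")

    def jassby_platt(I, p_max, alpha):
        return p_max * np.tanh(alpha * np.asarray(I, float) / p_max)

    popt, _ = _multistart_fit(
        jassby_platt, light, y, _starts(light, y),
        bounds=([1e-9, 1e-9], [np.inf, np.inf]),
    )
    return float(popt[1])


@dataclass(frozen=True)
class Spectrum:
    """A 400-700 nm spectrum at (nominally) 1 nm: absorbance, a*_ph, or
    spectral irradiance, tagged by ``kind``."""

    wavelength: np.ndarray
    value: np.ndarray
    kind: str = "absorbance"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if wl.shape != v.shape or wl.ndim != 1:
            raise DomainError("wavelength and value must be 1-D and equal length")
        if np.any(np.diff(wl) <= 0):
            raise DomainError("wavelengths must be strictly increasing")
        if wl[0] > 400.0 or wl[-1] < 700.0:
            raise DomainError("spectrum must span [400, 700] nm")
        if self.kind in ("a_star", "irradiance") and np.any(v < 0):
            raise DomainError(f"{self.kind} spectrum must be non-negative")
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "value", v)

    def resample(self, grid: np.ndarray) -> "Spectrum":
        return Spectrum(grid, np.interp(grid, self.wavelength, self.value), self.kind)


_PAR_GRID = np.arange(400.0, 700.0 + 1.0, 1.0)


def specific_absorption(
    absorbance: Spectrum, chla_mg_m3: float, path_m: float
) -> Spectrum:
    """Chlorophyll-specific absorption a*_ph(lambda) = ln(10) A(lambda) /
    ([Chla] x), m^2 mg-1 Chla.

    The ln(10) converts decadic absorbance to a natural-log absorption
    coefficient before normalizing by the Chla column density.
    """
    if chla_mg_m3 <= 0 or path_m <= 0:
        raise DomainError("chla and path length must be positive")
    return Spectrum(
        absorbance.wavelength,
        np.log(10.0) * absorbance.value / (chla_mg_m3 * path_m),
        kind="a_star",
    )


def absorbed_quanta(a_star: Spectrum, e0: Spectrum) -> float:
    """Absorbed photon flux, umol quanta mg-1 Chla s-1.

    Trapezoidal integral of a*_ph(lambda) E_0(lambda) over 400-700 nm; the
    spectra are linearly resampled onto the finer of their grids first.
    """
    grid = (
        a_star.wavelength
        if len(a_star.wavelength) >= len(e0.wavelength)
        else e0.wavelength
    )
    grid = grid[(grid >= 400.0) & (grid <= 700.0)]
    prod = a_star.resample(grid).value * e0.resample(grid).value
    return float(np.trapezoid(prod, grid))


def quantum_yield(p_chl_per_h: float, absorbed_per_s: float) -> float:
    """Phi = (P_chl / 3600) / absorbed photon flux; mol per mol quanta."""
    if absorbed_per_s <= 0.0:
        raise DomainError("absorbed photon flux must be positive")
    return (p_chl_per_h / 3600.0) / absorbed_per_s


@dataclass
class PhiSeries:
    """Quantum yield vs irradiance for carbon and/or oxygen.

    Yields are evaluated from the fitted net P-vs-E curves on a 1 umol-step
    irradiance grid; ``phi_max`` and ``E_at_phi_max`` locate the peak of each
    Phi-vs-E curve; ``PQ_at_Pmax`` is P_max(O2)/P_max(C) when both gases are
    available.
    """

    E: np.ndarray
    phi: dict[str, np.ndarray]
    phi_max: dict[str, float]
    E_at_phi_max: dict[str, float]
    PQ_at_Pmax: float | None


def normalize_to_unit_par(shape: Spectrum) -> Spectrum:
    """Scale an irradiance spectrum so its 400-700 nm integral is 1."""
    total = float(np.trapezoid(
        shape.resample(_PAR_GRID).value, _PAR_GRID
    ))
    if total <= 0:
        raise DomainError("lamp spectrum integrates to zero PAR")
    return Spectrum(shape.wavelength, shape.value / total, kind="irradiance")


def phi_series(
    fits: dict[str, PvEFit],
    a_star: Spectrum,
    lamp_shape: Spectrum,
    grid_step: float = 1.0,
) -> PhiSeries:
    """Quantum-yield series from fitted P-vs-E curves and the optical model.

    For each irradiance E on the grid, the spectral irradiance is the lamp
    shape (normalized to unit PAR) scaled by E; Phi(E) = P_net(E)/3600 over
    the absorbed flux. Because the net curve subtracts respiration, Phi peaks
    at intermediate E; the peak value and its location are reported per gas.
    """
    if not fits:
        raise InsufficientDataError("need a fitted P-vs-E curve for at least one gas")
    shape = normalize_to_unit_par(lamp_shape)
    absorbed_per_unit_E = absorbed_quanta(a_star, shape)
    some_fit = next(iter(fits.values()))
    pos = some_fit.light[some_fit.light > 0]
    E = np.arange(float(pos.min()), float(some_fit.light.max()) + grid_step, grid_step)

    phi: dict[str, np.ndarray] = {}
    phi_max: dict[str, float] = {}
    e_at: dict[str, float] = {}
    for gas, fit in fits.items():
        p_net = fit.predict(E)
        if np.all(p_net <= 0.0):
            raise DomainError(
                f"net {gas} curve non-positive over the whole grid (all respiration)"
            )
        y = (p_net / 3600.0) / (absorbed_per_unit_E * E)
        y[p_net <= 0.0] = np.nan
        if np.nanmax(y) >= PHI_CEILING:
            warnings.warn(
                f"Phi_{gas} exceeds the physical ceiling {PHI_CEILING}",
                category=SanityFlagWarning,
                stacklevel=2,
            )
        phi[gas] = y
        i = int(np.nanargmax(y))
        phi_max[gas] = float(y[i])
        e_at[gas] = float(E[i])

    pq = None
    if "oxygen" in fits and "carbon" in fits:
        pq = fits["oxygen"].P_max / fits["carbon"].P_max
    return PhiSeries(E=E, phi=phi, phi_max=phi_max, E_at_phi_max=e_at, PQ_at_Pmax=pq)


def growth_pchl(mu_per_h: float, poc: float, chla: float) -> float:
    """Chla-specific carbon uptake implied by exponential growth.

    P_Chl = mu [POC]/[Chla] converted from g C (g Chla)-1 h-1 to
    umol C mg-1 Chla h-1 (x 1000/12.011). POC and Chla must share units.
    """
    if mu_per_h < 0 or poc <= 0 or chla <= 0:
        raise DomainError("mu must be >= 0 and poc, chla positive")
    return mu_per_h * (poc / chla) * (1000.0 / 12.011)


def cn_ratio(carbon: float, nitrogen: float) -> float:
    """Cellular C:N mass ratio from per-cell quotas (same units)."""
    if carbon <= 0 or nitrogen <= 0:
        raise DomainError("carbon and nitrogen quotas must be positive")
    return carbon / nitrogen


def white_led_spectrum() -> Spectrum:
    """Generic white-LED emission shape, unit PAR integral.

    Blue InGaN peak near 450 nm over a broad phosphor band near 560 nm; a
    stand-in for the (unpublished) lamp spectrum, replaceable by a measured
    spectrum through the config.
    """
    wl = _PAR_GRID
    blue = np.exp(-0.5 * ((wl - 450.0) / 12.0) ** 2)
    phosphor = 0.75 * np.exp(-0.5 * ((wl - 560.0) / 55.0) ** 2)
    return normalize_to_unit_par(Spectrum(wl, blue + phosphor, kind="irradiance"))
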