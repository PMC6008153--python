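"""Seawater CO2-system engine.

Everything the pH-oscillation method needs from marine carbonate chemistry:
stoichiometric equilibrium constants on the total hydrogen-ion scale,
decomposition of total alkalinity A_T into its carbonate part A_c, DIC
speciation at measured pH, the inverse pH-from-DIC solve used by the forward
simulator, the Tris-buffer pH polynomial used to move electrode readings from
the NBS to the total scale, and Gran-titration reduction of alkalinity data.

Unit conventions
----------------
All equilibrium math runs internally in mol kg-sw^-1; the public API takes and
returns micromol kg^-1 (the working unit of the incubation pipeline).
Conversions to volumetric units use the medium density field. pH is on the
total scale throughout ([H+] = 10**-pH_T); total-scale constants absorb the
free/sulfate partitioning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    BracketError,
    DomainError,
    InconsistentChemistryError,
    InsufficientDataError,
    PoorLinearityWarning,
    SuspectCalibrationWarning,
)

__all__ = [
    "MediumChemistry",
    "EquilibriumConstants",
    "CarbonateSpeciation",
    "TitrationRecord",
    "GranResult",
    "borate_from_salinity",
    "equilibrium_constants",
    "carbonate_alkalinity",
    "speciate_from_ph",
    "dic_from_ph",
    "ph_from_dic",
    "ph_from_alkalinity_dic",
    "total_alkalinity_from_ph",
    "tris_ph",
    "nbs_to_total",
    "gran_alkalinity",
]

#: Uppstrom (1974) total boron of natural seawater at S=35, umol kg-1.
_BORON_AT_S35 = 415.7


def borate_from_salinity(salinity: float) -> float:
    """Total borate (umol kg-1) scaled linearly with salinity (Uppstrom 1974)."""
    return _BORON_AT_S35 * salinity / 35.0


@dataclass(frozen=True)
class MediumChemistry:
    """Salinity/temperature/alkalinity/nutrient description of the medium.

    Parameters
    ----------
    salinity : practical salinity (dimensionless)
    temperature : K
    total_alkalinity : A_T, umol kg-1
    density : kg L-1, used for umol kg-1 <-> umol L-1 conversions
    total_borate : B_T, umol kg-1; default scales Uppstrom boron with salinity
    total_phosphate : P_T, umol kg-1
    total_silicate : Si_T, umol kg-1
    """

    salinity: float
    temperature: float
    total_alkalinity: float
    density: float = 1.0352
    total_borate: float | None = None
    total_phosphate: float = 0.0
    total_silicate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.salinity <= 45.0:
            raise DomainError(f"salinity {self.salinity} outside [0, 45]")
        if not 270.0 <= self.temperature <= 315.0:
            raise DomainError(f"temperature {self.temperature} K outside [270, 315]")
        if not self.total_alkalinity > 0.0:
            raise DomainError("total_alkalinity must be positive")
        if not self.density > 0.9:
            raise DomainError("density must exceed 0.9 kg/L")
        if self.total_borate is None:
            object.__setattr__(
                self, "total_borate", borate_from_salinity(self.salinity)
            )
        for name in ("total_borate", "total_phosphate", "total_silicate"):
            if getattr(self, name) < 0.0:
                raise DomainError(f"{name} must be non-negative")


@dataclass(frozen=True)
class EquilibriumConstants:
    """Stoichiometric dissociation constants, mol kg-1, total scale."""

    K1: float
    K2: float
    KB: float
    KW: float
    K1P: float
    K2P: float
    K3P: float
    KSi: float

    def __post_init__(self) -> None:
        for name in ("K1", "K2", "KB", "KW", "K1P", "K2P", "K3P", "KSi"):
            if not getattr(self, name) > 0.0:
                raise DomainError(f"{name} must be positive")
        if not self.K1 > self.K2:
            raise DomainError("carbonic acid requires K1 > K2")


class CarbonateSpeciation(NamedTuple):
    """One carbonate-system state; concentrations in umol kg-1."""

    pH_T: float
    H: float  # mol kg-1
    CO2: float
    HCO3: float
    CO3: float
    DIC: float
    A_c: float


def _lueker2000(chem: MediumChemistry) -> EquilibriumConstants:
    """Total-scale constant set per the Guide to Best Practices.

    K1/K2: Lueker et al. (2000); KB: Dickson (1990); KW: Millero (1995);
    phosphoric and silicic constants: Millero (1995) as compiled in the Guide.
    """
    S, T = chem.salinity, chem.temperature
    lnT = np.log(T)
    sqS = np.sqrt(S)

    pK1 = 3633.86 / T - 61.2172 + 9.67770 * lnT - 0.011555 * S + 0.0001152 * S**2
    pK2 = 471.78 / T + 25.9290 - 3.16967 * lnT - 0.01781 * S + 0.0001122 * S**2

    lnKB = (
        (-8966.90 - 2890.53 * sqS - 77.942 * S + 1.728 * S**1.5 - 0.0996 * S**2) / T
        + (148.0248 + 137.1942 * sqS + 1.62142 * S)
        + (-24.4344 - 25.085 * sqS - 0.2474 * S) * lnT
        + 0.053105 * sqS * T
    )
    lnKW = (
        148.9802
        - 13847.26 / T
        - 23.6521 * lnT
        + (118.67 / T - 5.977 + 1.0495 * lnT) * sqS
        - 0.01615 * S
    )
    lnK1P = (
        -4576.752 / T
        + 115.525
        - 18.453 * lnT
        + (-106.736 / T + 0.69171) * sqS
        + (-0.65643 / T - 0.01844) * S
    )
    lnK2P = (
        -8814.715 / T
        + 172.0883
        - 27.927 * lnT
        + (-160.340 / T + 1.3566) * sqS
        + (0.37335 / T - 0.05778) * S
    )
    lnK3P = (
        -3070.75 / T
        - 18.141
        + (17.27039 / T + 2.81197) * sqS
        + (-44.99486 / T - 0.09984) * S
    )
    # Silicic acid uses ionic strength rather than salinity directly.
    Is = 19.924 * S / (1000.0 - 1.005 * S)
    lnKSi = (
        -8904.2 / T
        + 117.385
        - 19.334 * lnT
        + (-458.79 / T + 3.5913) * np.sqrt(Is)
        + (188.74 / T - 1.5998) * Is
        + (-12.1652 / T + 0.07871) * Is**2
        + np.log(1.0 - 0.001005 * S)
    )
    return EquilibriumConstants(
        K1=10.0**-pK1,
        K2=10.0**-pK2,
        KB=np.exp(lnKB),
        KW=np.exp(lnKW),
        K1P=np.exp(lnK1P),
        K2P=np.exp(lnK2P),
        K3P=np.exp(lnK3P),
        KSi=np.exp(lnKSi),
    )


CONSTANT_SETS: dict[str, Callable[[MediumChemistry], EquilibriumConstants]] = {
    "lueker2000": _lueker2000,
}


def equilibrium_constants(
    chem: MediumChemistry, constants: str = "lueker2000"
) -> EquilibriumConstants:
    """Stoichiometric constants at the medium's salinity and temperature.

    The constant set is a pluggable strategy keyed by name; register a callable
    in :data:`CONSTANT_SETS` (signature ``MediumChemistry ->
    EquilibriumConstants``) to use a custom parameterization.
    """
    try:
        strategy = CONSTANT_SETS[constants]
    except KeyError:
        raise DomainError(
            f"unknown constant set {constants!r}; available: {sorted(CONSTANT_SETS)}"
        ) from None
    return strategy(chem)


def _check_ph(pH_T) -> np.ndarray:
    pH = np.asarray(pH_T, dtype=float)
    if np.any(pH < 6.0) or np.any(pH > 10.0):
        raise DomainError("pH_T outside supported range [6, 10]")
    return pH


def _minor_alkalinity(chem: MediumChemistry, H: np.ndarray, k: EquilibriumConstants):
    """Non-carbonate alkalinity terms in mol kg-1 at hydrogen ion H (mol kg-1).

    Returns (borate, hydroxide, HPO4, PO4, H3PO4, silicate).
    """
    BT = chem.total_borate * 1e-6
    PT = chem.total_phosphate * 1e-6
    SiT = chem.total_silicate * 1e-6
    boh4 = BT * k.KB / (k.KB + H)
    oh = k.KW / H
    pden = H**3 + k.K1P * H**2 + k.K1P * k.K2P * H + k.K1P * k.K2P * k.K3P
    hpo4 = PT * k.K1P * k.K2P * H / pden
    po4 = PT * k.K1P * k.K2P * k.K3P / pden
    h3po4 = PT * H**3 / pden
    sioh3 = SiT * k.KSi / (k.KSi + H)
    return boh4, oh, hpo4, po4, h3po4, sioh3


def carbonate_alkalinity(
    chem: MediumChemistry, pH_T, k: EquilibriumConstants
):
    """Carbonate alkalinity A_c (umol kg-1) from A_T and total-scale pH.

    A_c = A_T - [B(OH)4-] - [OH-] - [HPO4 2-] - 2[PO4 3-] - [SiO(OH)3-]
          + [H3PO4]

    Accepts scalar or array pH; vectorizes elementwise.
    """
    pH = _check_ph(pH_T)
    H = 10.0 ** (-pH)
    boh4, oh, hpo4, po4, h3po4, sioh3 = _minor_alkalinity(chem, H, k)
    AT = chem.total_alkalinity * 1e-6
    ac = AT - boh4 - oh - hpo4 - 2.0 * po4 - sioh3 + h3po4
    if np.any(ac <= 0.0):
        raise InconsistentChemistryError(
            "carbonate alkalinity non-positive after subtracting minor bases"
        )
    out = ac * 1e6
    return float(out) if np.isscalar(pH_T) else out


def speciate_from_ph(pH_T, A_c, k: EquilibriumConstants) -> CarbonateSpeciation:
    """Full DIC speciation at a given total-scale pH and carbonate alkalinity.

    [CO2]  = A_c H^2 / (K1 (H + 2 K2))
    [HCO3] = A_c H / (H + 2 K2)
    [CO3]  = A_c K2 / (H + 2 K2)

    and DIC is their sum. The identity [HCO3] + 2[CO3] = A_c is exact in this
    parameterization. Units: A_c and outputs in umol kg-1.
    """
    if np.any(np.asarray(A_c) <= 0.0):
        raise DomainError("A_c must be positive")
    pH = _check_ph(pH_T)
    H = 10.0 ** (-pH)
    den = H + 2.0 * k.K2
    co2 = A_c * H**2 / (k.K1 * den)
    hco3 = A_c * H / den
    co3 = A_c * k.K2 / den
    dic = co2 + hco3 + co3
    if np.isscalar(pH_T) and np.isscalar(A_c):
        return CarbonateSpeciation(
            float(pH), float(H), float(co2), float(hco3), float(co3), float(dic),
            float(A_c),
        )
    return CarbonateSpeciation(pH, H, co2, hco3, co3, dic, np.broadcast_to(
        np.asarray(A_c, dtype=float), np.shape(dic)
    ))


def dic_from_ph(
    pH_T, chem: MediumChemistry, k: EquilibriumConstants
) -> CarbonateSpeciation:
    """Speciation at measured pH under the medium's (constant) A_T."""
    ac = carbonate_alkalinity(chem, pH_T, k)
    return speciate_from_ph(pH_T, ac, k)


def ph_from_dic(
    dic_target: float,
    chem: MediumChemistry,
    k: EquilibriumConstants,
    bracket: tuple[float, float] = (6.0, 10.0),
    xtol: float = 1e-10,
) -> float:
    """Invert DIC(pH) at fixed A_T by bisection on pH in [6, 10].

    DIC is strictly decreasing in pH at fixed alkalinity, so the root is
    unique whenever the target lies between DIC(pH=10) and DIC(pH=6).
    """
    lo, hi = bracket

    def f(ph: float) -> float:
        return dic_from_ph(ph, chem, k).DIC - dic_target

    flo, fhi = f(lo), f(hi)
    if flo < 0.0 or fhi > 0.0:
        raise BracketError(
            f"DIC target {dic_target:.3f} umol/kg not bracketed by pH in "
            f"[{lo}, {hi}] (range {f(hi) + dic_target:.3f} .. "
            f"{f(lo) + dic_target:.3f})"
        )
    return float(optimize.bisect(f, lo, hi, xtol=xtol))


def total_alkalinity_from_ph(
    pH_T: float, dic: float, chem: MediumChemistry, k: EquilibriumConstants
) -> float:
    """Total alkalinity (umol kg-1) from pH and DIC via the full charge balance.

    Used by the titration forward model, which must track alkalinity through
    and past the equivalence point; unlike the incubation-range Eq for A_c it
    keeps the -[H+] closing term, so it is valid down to pH ~ 2.
    """
    H = 10.0 ** (-pH_T)
    den = H**2 + k.K1 * H + k.K1 * k.K2
    hco3 = dic * 1e-6 * k.K1 * H / den
    co3 = dic * 1e-6 * k.K1 * k.K2 / den
    boh4, oh, hpo4, po4, h3po4, sioh3 = _minor_alkalinity(
        chem, np.asarray(H), k
    )
    at = hco3 + 2.0 * co3 + boh4 + oh + hpo4 + 2.0 * po4 + sioh3 - h3po4 - H
    return float(at * 1e6)


def ph_from_alkalinity_dic(
    alkalinity: float,
    dic: float,
    chem: MediumChemistry,
    k: EquilibriumConstants,
    bracket: tuple[float, float] = (1.5, 10.5),
) -> float:
    """Solve the full charge balance for pH given (A_T, DIC).

    Covers acid-titrated samples (negative alkalinity allowed); root solve by
    Brent's method on the monotone A_T(pH) curve.
    """

    def f(ph: float) -> float:
        return total_alkalinity_from_ph(ph, dic, chem, k) - alkalinity

    lo, hi = bracket
    if f(lo) > 0.0 or f(hi) < 0.0:
        raise BracketError("alkalinity/DIC pair not bracketed in pH")
    return float(optimize.brentq(f, lo, hi, xtol=1e-11))


def tris_ph(salinity: float, temperature_K: float) -> float:
    """Total-scale pH of Tris-buffered synthetic seawater (DelValls & Dickson).

    pH_Tris = (11911.08 - 18.2499 S - 0.039336 S^2)/T
              + (-366.27059 + 0.53993607 S + 0.00016329 S^2)
              + (64.52243 - 0.084041 S) ln T - 0.11149858 T
    """
    S, T = salinity, temperature_K
    if not 20.0 <= S <= 40.0:
        raise DomainError(f"salinity {S} outside Tris polynomial range [20, 40]")
    if not 273.0 <= T <= 318.0:
        raise DomainError(f"temperature {T} K outside Tris polynomial range")
    return (
        (11911.08 - 18.2499 * S - 0.039336 * S**2) / T
        + (-366.27059 + 0.53993607 * S + 0.00016329 * S**2)
        + (64.52243 - 0.084041 * S) * np.log(T)
        - 0.11149858 * T
    )


def nbs_to_total(pH_m, pH_m_tris: float, pH_cal_tris: float):
    """Move an electrode pH reading from the NBS to the total scale.

    pH_T = pH_m - (pH_m_Tris - pH_cal_Tris): a single Tris-in-synthetic-
    seawater measurement pins the liquid-junction offset, assuming equal
    electrode E0 in Tris buffer and in the culture medium. Offsets beyond
    0.5 pH are flagged as suspect but still applied.
    """
    offset = pH_m_tris - pH_cal_tris
    if abs(offset) > 0.5:
        warnings.warn(
            f"Tris offset {offset:+.3f} pH exceeds 0.5; electrode calibration "
            "suspect",
            category=SuspectCalibrationWarning,
            stacklevel=2,
        )
    return pH_m - offset


@dataclass(frozen=True)
class TitrationRecord:
    """One Gran titration: open-cell acid additions into a weighed sample.

    ``acid_amount`` is cumulative (g or mL per ``amount_unit``) and strictly
    increasing; pH is on the total scale and strictly decreasing.
    ``acid_concentration`` is mol kg-1 when amounts are masses, mol L-1 when
    they are volumes.
    """

    sample_mass: float  # g
    acid_concentration: float
    points: tuple[tuple[float, float], ...]
    amount_unit: str = "g"

    def __post_init__(self) -> None:
        if self.amount_unit not in ("g", "mL"):
            raise DomainError("amount_unit must be 'g' or 'mL'")
        if self.sample_mass <= 0 or self.acid_concentration <= 0:
            raise DomainError("sample mass and acid concentration must be positive")
        if len(self.points) < 5:
            raise InsufficientDataError("a titration needs at least 5 points")
        amounts = np.array([p[0] for p in self.points])
        phs = np.array([p[1] for p in self.points])
        if np.any(np.diff(amounts) <= 0):
            raise DomainError("acid amounts must be strictly increasing")
        if np.any(np.diff(phs) >= 0):
            raise DomainError("titration pH must be strictly decreasing")


class GranResult(NamedTuple):
    A_T: float  # umol kg-1
    equivalence_amount: float  # same unit as acid_amount
    r2: float
    n_points: int


def gran_alkalinity(
    t: TitrationRecord, ph_cutoff: float = 3.8, r2_warn: float = 0.995
) -> GranResult:
    """Total alkalinity by the Gran method.

    In the acid-excess region (pH_T < ``ph_cutoff``) the Gran function
    F = (m0 + m) 10**(-pH_T) is linear in added acid m and crosses zero at the
    equivalence amount m_e; A_T = m_e x [acid] / m0. Requires >= 4 qualifying
    points; warns if the Gran line's r^2 falls below ``r2_warn``.
    """
    amounts = np.array([p[0] for p in t.points])
    phs = np.array([p[1] for p in t.points])
    mask = phs < ph_cutoff
    if mask.sum() < 4:
        raise InsufficientDataError(
            f"only {int(mask.sum())} titration points below pH {ph_cutoff}; "
            "need >= 4 in the acid-excess region"
        )
    m = amounts[mask]
    F = (t.sample_mass + m) * 10.0 ** (-phs[mask])
    fit = stats.linregress(m, F)
    r2 = fit.rvalue**2
    if r2 < r2_warn:
        warnings.warn(
            f"Gran line r^2 = {r2:.5f} below {r2_warn}",
            category=PoorLinearityWarning,
            stacklevel=2,
        )
    m_e = -fit.intercept / fit.slope
    # moles of acid at equivalence: conc is mol/kg with gram amounts or
    # mol/L with mL amounts; both give mol when divided by 1000.
    acid_mol = t.acid_concentration * m_e / 1000.0
    at = acid_mol / (t.sample_mass / 1000.0) * 1e6
    return GranResult(A_T=float(at), equivalence_amount=float(m_e), r2=float(r2),
                      n_points=int(mask.sum()))
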