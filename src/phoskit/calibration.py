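"""Sensor calibration math for the pHOS-MIMS instrument.

Covers the glass pH electrode (buffer-line fit with a Nernst-slope quality
gate), the ADC resolution arithmetic that sets the pH detection floor, oxygen
solubility (Garcia & Gordon Benson-Krause fit), and the two-point O2/Ar
ratio calibration of the membrane-inlet mass spectrometer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import CalibrationError, DomainError

__all__ = [
    "ElectrodeCalibration",
    "OxygenCalibration",
    "nernst_slope_mv",
    "fit_electrode",
    "voltage_to_ph",
    "adc_ph_resolution",
    "oxygen_saturation",
    "oxygen_from_signal",
]

# Physical constants (CODATA)
_R = 8.31446261815324  # J mol-1 K-1
_F = 96485.33212331001  # C mol-1


def nernst_slope_mv(temperature_K: float) -> float:
    """Ideal electrode slope magnitude ln(10)RT/F in mV per pH unit.

    59.16 mV/pH at 298.15 K.
    """
    return np.log(10.0) * _R * temperature_K / _F * 1000.0


@dataclass(frozen=True)
class ElectrodeCalibration:
    """Voltage-vs-pH calibration line for a glass electrode.

    ``slope`` (mV per pH) is negative for the standard wiring; the
    ``nernst_ratio`` is |slope| over the ideal ln(10)RT/F slope and must fall
    in [0.9, 1.05] to pass QC. ``tris_offset`` (pH_m_Tris - pH_cal_Tris) moves
    NBS-scale readings onto the total scale downstream.
    """

    slope: float
    intercept: float
    buffer_points: tuple[tuple[float, float], ...]
    nernst_ratio: float
    temperature: float
    tris_offset: float = 0.0


@dataclass(frozen=True)
class OxygenCalibration:
    """Two-point O2/Ar calibration: air-saturated and dithionite-zeroed medium."""

    r_sat: float
    r_zero: float
    O2_sat: float  # umol kg-1 at the calibration S, T, P

    def __post_init__(self) -> None:
        if not self.r_sat > self.r_zero >= 0.0:
            raise CalibrationError("require r_sat > r_zero >= 0")
        if not self.O2_sat > 0.0:
            raise CalibrationError("O2_sat must be positive")


def fit_electrode(
    buffer_points,
    temperature_K: float,
    ratio_band: tuple[float, float] = (0.9, 1.05),
    tris_offset: float = 0.0,
) -> ElectrodeCalibration:
    """Least-squares electrode line from standard-buffer readings.

    ``buffer_points`` is a sequence of (pH_NBS, voltage_mV) pairs (typically a
    3-point calibration). The fitted slope is compared with the ideal Nernst
    slope at the calibration temperature; electrodes whose response magnitude
    falls outside ``ratio_band`` of ideal are rejected.
    """
    pts = np.asarray(buffer_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise DomainError("need at least two (pH, voltage) buffer points")
    ph, mv = pts[:, 0], pts[:, 1]
    if np.ptp(ph) == 0.0:
        raise CalibrationError("buffer pH values are all identical; singular fit")
    fit = stats.linregress(ph, mv)
    ratio = abs(fit.slope) / nernst_slope_mv(temperature_K)
    lo, hi = ratio_band
    if not lo <= ratio <= hi:
        raise CalibrationError(
            f"electrode slope {fit.slope:.2f} mV/pH is {ratio:.3f} of the ideal "
            f"Nernst slope; outside the pass band [{lo}, {hi}]"
        )
    return ElectrodeCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        buffer_points=tuple(map(tuple, pts)),
        nernst_ratio=float(ratio),
        temperature=float(temperature_K),
        tris_offset=float(tris_offset),
    )


def voltage_to_ph(voltage_mV, cal: ElectrodeCalibration):
    """Invert the calibration line: pH_NBS = (V - intercept)/slope.

    Vectorizes over a full trace; output length equals input length.
    """
    return (np.asarray(voltage_mV, dtype=float) - cal.intercept) / cal.slope


def adc_ph_resolution(
    mv_per_bit: float, amplifier_gain: float, temperature_K: float
) -> float:
    """pH change represented by one ADC bit.

    The ADC sees the electrode voltage after amplification, so one bit spans
    mv_per_bit / gain at the electrode, which divided by the Nernst slope
    gives pH units per bit. At the instrument's 0.1875 mV/bit and 2.2 V/V
    this is ~0.0015 pH.
    """
    if mv_per_bit <= 0 or amplifier_gain <= 0 or temperature_K <= 0:
        raise DomainError("all adc_ph_resolution inputs must be positive")
    return (mv_per_bit / amplifier_gain) / nernst_slope_mv(temperature_K)


# Garcia & Gordon (1992) combined (Benson & Krause) fit, umol kg-1.
_GG_A = (5.80871, 3.20291, 4.17887, 5.10006, -9.86643e-2, 3.80369)
_GG_B = (-7.01577e-3, -7.70028e-3, -1.13864e-2, -9.51519e-3)
_GG_C0 = -2.75915e-7


def oxygen_saturation(
    salinity: float, temperature_K: float, pressure_atm: float = 1.0
) -> float:
    """Air-saturated dissolved O2 (umol kg-1), Garcia & Gordon (1992).

    Benson-Krause combined-fit coefficients in the scaled-temperature form;
    check value 274.61 umol kg-1 at S=35, t=10 C, 1 atm. Pressure enters as a
    linear scaling about 1 atm.
    """
    if not 0.0 <= salinity <= 42.0:
        raise DomainError(f"salinity {salinity} outside [0, 42]")
    if not 271.0 <= temperature_K <= 313.0:
        raise DomainError(f"temperature {temperature_K} K outside [271, 313]")
    t_c = temperature_K - 273.15
    ts = np.log((298.15 - t_c) / (273.15 + t_c))
    lnc = sum(a * ts**i for i, a in enumerate(_GG_A))
    lnc += salinity * sum(b * ts**i for i, b in enumerate(_GG_B))
    lnc += _GG_C0 * salinity**2
    return float(np.exp(lnc) * pressure_atm)


def oxygen_from_signal(r, cal: OxygenCalibration):
    """Dissolved O2 (umol kg-1) from an O2/Ar signal ratio.

    Linear two-point calibration: O2 = O2_sat (r - r_zero)/(r_sat - r_zero).
    Values above O2_sat are valid (photosynthetic supersaturation in the
    closed cell). Because both channels ride the same vacuum pressure, any
    common multiplicative drift cancels in the ratio.
    """
    if cal.r_sat == cal.r_zero:
        raise CalibrationError("degenerate O2 calibration: r_sat == r_zero")
    r = np.asarray(r, dtype=float)
    out = cal.O2_sat * (r - cal.r_zero) / (cal.r_sat - cal.r_zero)
    return float(out) if out.ndim == 0 else out
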