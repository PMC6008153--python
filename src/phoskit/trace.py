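"""Oscillation-trace reduction: from a calibrated 1 Hz time series to
per-light-step DIC-uptake and O2-evolution rates.

The measurement protocol alternates 2-min dark and light periods at stepped
irradiance. Within each period the medium pH drifts as the cells take up or
release DIC; converting pH to DIC at constant alkalinity and fitting a line
to each period turns the drift into a rate. O2 follows the same path through
the O2/Ar ratio calibration. Rates are normalized to chlorophyll a and hours:
positive rate_DIC is uptake, positive rate_O2 is evolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from . import carbonate as cb
from .calibration import ElectrodeCalibration, OxygenCalibration, oxygen_from_signal, voltage_to_ph
from .errors import (
    ConfigError,
    DomainError,
    InsufficientDataError,
    ProtocolError,
)

__all__ = [
    "OscillationTrace",
    "Segment",
    "SegmentRate",
    "segment_trace",
    "segment_slope",
    "trace_to_dic",
    "pve_points",
]


@dataclass
class OscillationTrace:
    """Multichannel 1 Hz record of one pHOS-MIMS incubation.

    ``ph`` holds total-scale pH when ``ph_is_total`` (the default after
    calibration), otherwise raw electrode voltage in mV. Light is the
    commanded irradiance per sample (umol quanta m-2 s-1) and is piecewise
    constant over the protocol steps.
    """

    time: np.ndarray
    ph: np.ndarray
    o2_signal: np.ndarray
    ar_signal: np.ndarray
    light: np.ndarray
    temperature: float
    chemistry: cb.MediumChemistry
    chla: float  # ug mL-1 == mg L-1
    od750: float = 0.0
    ph_is_total: bool = True

    def __post_init__(self) -> None:
        arrs = [np.asarray(a, dtype=float) for a in
                (self.time, self.ph, self.o2_signal, self.ar_signal, self.light)]
        n = len(arrs[0])
        if any(len(a) != n for a in arrs):
            raise DomainError("all trace channels must share one length")
        if np.any(np.diff(arrs[0]) <= 0):
            raise DomainError("trace time must be strictly increasing")
        self.time, self.ph, self.o2_signal, self.ar_signal, self.light = arrs

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class Segment:
    """One contiguous constant-light span of a trace (sample index slice)."""

    start: int
    stop: int
    light_level: float

    @property
    def is_dark(self) -> bool:
        return self.light_level == 0.0


@dataclass(frozen=True)
class SegmentRate:
    """Chla-normalized rates for one protocol step.

    rate_DIC: umol C mg-1 Chla h-1, positive = uptake.
    rate_O2:  umol O2 mg-1 Chla h-1, positive = evolution.
    Raw per-second concentration slopes (umol kg-1 s-1) and their fit
    diagnostics are kept for QC.
    """

    light_level: float
    rate_DIC: float
    rate_O2: float
    slope_DIC: float
    slope_O2: float
    se_DIC: float
    se_O2: float
    n_points: int
    r2_DIC: float
    r2_O2: float


def _detect_steps(light: np.ndarray) -> list[tuple[int, int, float]]:
    """Runs of constant light: list of (start, stop, level)."""
    edges = np.flatnonzero(np.diff(light) != 0.0) + 1
    bounds = np.concatenate(([0], edges, [len(light)]))
    return [
        (int(a), int(b), float(light[a])) for a, b in zip(bounds[:-1], bounds[1:])
    ]


def segment_trace(
    trace: OscillationTrace,
    schedule: Sequence[tuple[float, float]] | None = None,
    max_mismatch_s: float = 5.0,
) -> list[Segment]:
    """Cut a trace into constant-light segments.

    With a declared ``schedule`` (list of (duration_s, light_level)) the cuts
    follow the schedule and are cross-checked against the light channel: a
    transition disagreeing by more than ``max_mismatch_s`` raises. Without a
    schedule, segmentation is detected from the light channel alone.
    """
    detected = _detect_steps(trace.light)
    if schedule is None:
        return [Segment(a, b, lvl) for a, b, lvl in detected]

    dt = float(np.median(np.diff(trace.time)))
    total = sum(d for d, _ in schedule)
    if total > trace.time[-1] - trace.time[0] + dt * 1.5:
        raise ProtocolError("declared schedule is longer than the trace")

    segments: list[Segment] = []
    t0 = trace.time[0]
    cursor = t0
    for duration, level in schedule:
        start = int(np.searchsorted(trace.time, cursor - 1e-9))
        stop = int(np.searchsorted(trace.time, cursor + duration - 1e-9))
        segments.append(Segment(start, stop, float(level)))
        cursor += duration

    # Verify the light channel agrees with the declared transitions.
    det_edges = {a for a, _, _ in detected[1:]}
    for seg in segments[1:]:
        t_decl = trace.time[seg.start]
        nearest = min(
            (abs(trace.time[e] - t_decl) for e in det_edges), default=np.inf
        )
        if nearest > max_mismatch_s:
            raise ProtocolError(
                f"declared transition at t={t_decl:.0f}s has no light-channel "
                f"edge within {max_mismatch_s}s"
            )
    return segments


def segment_slope(
    values: np.ndarray,
    time: np.ndarray,
    trim_s: float = 10.0,
    min_points: int = 30,
) -> tuple[float, float, float]:
    """OLS slope of a concentration series vs time after trimming the
    segment start.

    The first ``trim_s`` seconds are dropped (electrode and membrane settle
    after each light transition). Returns (slope per s, standard error, r^2).
    """
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = time >= time[0] + trim_s
    if keep.sum() < min_points:
        raise InsufficientDataError(
            f"{int(keep.sum())} points after trimming {trim_s}s; need >= {min_points}"
        )
    fit = stats.linregress(time[keep], values[keep])
    return float(fit.slope), float(fit.stderr), float(fit.rvalue**2)


def trace_to_dic(
    trace: OscillationTrace, k: cb.EquilibriumConstants | None = None
) -> np.ndarray:
    """Per-sample DIC (umol kg-1) at the medium's constant total alkalinity."""
    if not trace.ph_is_total:
        raise ConfigError(
            "trace pH must be on the total scale; apply voltage_to_ph and "
            "nbs_to_total first"
        )
    if k is None:
        k = cb.equilibrium_constants(trace.chemistry)
    bad = (trace.ph < 6.0) | (trace.ph > 10.0)
    if np.any(bad):
        raise DomainError(
            f"pH outside [6, 10] at sample index {int(np.flatnonzero(bad)[0])}"
        )
    return np.asarray(cb.dic_from_ph(trace.ph, trace.chemistry, k).DIC)


def _o2_series(trace: OscillationTrace, o2_cal: OxygenCalibration) -> np.ndarray:
    return oxygen_from_signal(trace.o2_signal / trace.ar_signal, o2_cal)


def calibrate_trace_ph(
    trace: OscillationTrace, electrode_cal: ElectrodeCalibration
) -> OscillationTrace:
    """Convert a raw-voltage trace to total-scale pH using the electrode line
    and its Tris offset."""
    ph_nbs = voltage_to_ph(trace.ph, electrode_cal)
    ph_t = ph_nbs - electrode_cal.tris_offset
    out = replace(trace)
    out.ph = np.asarray(ph_t, dtype=float)
    out.ph_is_total = True
    return out


def pve_points(
    trace: OscillationTrace,
    o2_cal: OxygenCalibration | None = None,
    schedule: Sequence[tuple[float, float]] | None = None,
    trim_s: float = 10.0,
    k: cb.EquilibriumConstants | None = None,
) -> list[SegmentRate]:
    """Per-step photosynthesis rates for the P-vs-E curve.

    Uses the first dark segment (the respiration point, reported at light=0)
    and every light segment; later dark segments serve only as drift QC and
    are excluded, following the measurement protocol. The per-second DIC
    slope (umol kg-1 s-1) is converted to a Chla-specific hourly rate with
    the medium density:

        rate_DIC = -slope * density(kg/L) * 3600 / chla(mg/L)

    and analogously with +slope for O2 evolution.
    """
    if trace.chla <= 0.0:
        raise ConfigError("chla must be positive to normalize rates")
    if k is None:
        k = cb.equilibrium_constants(trace.chemistry)
    segments = segment_trace(trace, schedule)
    if not segments or not segments[0].is_dark:
        raise ProtocolError("protocol requires the trace to open with a dark segment")

    dic = trace_to_dic(trace, k)
    o2 = _o2_series(trace, o2_cal) if o2_cal is not None else None

    factor = trace.chemistry.density * 3600.0 / trace.chla
    rates: list[SegmentRate] = []
    first_dark_done = False
    for seg in segments:
        if seg.is_dark:
            if first_dark_done:
                continue
            first_dark_done = True
        sl = slice(seg.start, seg.stop)
        s_dic, se_dic, r2_dic = segment_slope(dic[sl], trace.time[sl], trim_s)
        if o2 is not None:
            s_o2, se_o2, r2_o2 = segment_slope(o2[sl], trace.time[sl], trim_s)
        else:
            s_o2 = se_o2 = r2_o2 = float("nan")
        rates.append(
            SegmentRate(
                light_level=seg.light_level,
                rate_DIC=-s_dic * factor,
                rate_O2=s_o2 * factor,
                slope_DIC=s_dic,
                slope_O2=s_o2,
                se_DIC=se_dic * factor,
                se_O2=se_o2 * factor,
                n_points=seg.stop - seg.start,
                r2_DIC=r2_dic,
                r2_O2=r2_o2,
            )
        )
    return rates
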