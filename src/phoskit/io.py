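"""File formats and run configuration.

Everything on disk is CSV (traces, spectra, titrations, fit tables) plus one
TOML run-config. Readers validate schemas and monotonicity and warn on data
gaps; writers round-trip with readers to float precision.
"""

from __future__ import annotations

import logging
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import carbonate as cb
from .errors import AttenuationWarning, ConfigError, DataGapWarning, SchemaError
from .photophys import Spectrum
from .qc import attenuation_fraction, max_od_for_loss
from .trace import OscillationTrace

__all__ = [
    "RunConfig",
    "read_trace_csv",
    "write_trace_csv",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_titration_csv",
    "write_fit_report",
]

log = logging.getLogger("phoskit")

#: Empirical PAR-attenuation coefficients of the measurement cuvette
#: (loss = exp(a*OD750 - b)); the 10% ceiling sits near OD750 = 0.35.
ATTENUATION_A = 9.12
ATTENUATION_B = 5.61
MAX_PAR_LOSS = 0.10

_TRACE_COLUMNS = {
    "ph": ["time_s", "ph", "o2_signal", "ar_signal", "light_umol_m2_s", "temp_c"],
    "voltage": [
        "time_s", "voltage_mv", "o2_signal", "ar_signal", "light_umol_m2_s", "temp_c",
    ],
}


def _check_od750(od750: float) -> None:
    if od750 > max_od_for_loss(ATTENUATION_A, ATTENUATION_B, MAX_PAR_LOSS):
        loss = attenuation_fraction(od750, ATTENUATION_A, ATTENUATION_B)
        warnings.warn(
            f"OD750 = {od750:.2f} attenuates ~{100 * loss:.0f}% of PAR at the "
            "cuvette center (ceiling 10%); rates at high light will be biased",
            category=AttenuationWarning,
            stacklevel=3,
        )


def read_trace_csv(
    path,
    chemistry: cb.MediumChemistry,
    chla: float,
    od750: float = 0.0,
    dialect: str = "ph",
    max_gap_s: float = 2.0,
) -> OscillationTrace:
    """Load an oscillation trace CSV.

    ``dialect`` declares the pH column: 'ph' (total-scale pH, calibrated
    upstream) or 'voltage' (raw electrode mV). Gaps longer than ``max_gap_s``
    are flagged but the trace still loads.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    try:
        cols = _TRACE_COLUMNS[dialect]
    except KeyError:
        raise ConfigError(f"unknown trace dialect {dialect!r}") from None
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"trace file {path} missing column(s): {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise SchemaError(f"non-monotone time at row {int(bad[0]) + 1}")
    gaps = np.flatnonzero(np.diff(t) > max_gap_s)
    if gaps.size:
        warnings.warn(
            f"{gaps.size} gap(s) > {max_gap_s}s in {path} (first after "
            f"t={t[gaps[0]]:.0f}s)",
            category=DataGapWarning,
            stacklevel=2,
        )
    _check_od750(od750)
    ph_col = "ph" if dialect == "ph" else "voltage_mv"
    return OscillationTrace(
        time=t,
        ph=df[ph_col].to_numpy(dtype=float),
        o2_signal=df["o2_signal"].to_numpy(dtype=float),
        ar_signal=df["ar_signal"].to_numpy(dtype=float),
        light=df["light_umol_m2_s"].to_numpy(dtype=float),
        temperature=float(df["temp_c"].iloc[0]) + 273.15,
        chemistry=chemistry,
        chla=chla,
        od750=od750,
        ph_is_total=(dialect == "ph"),
    )


def write_trace_csv(path, trace: OscillationTrace) -> None:
    """Write a trace in the standard CSV layout (pH dialect)."""
    pd.DataFrame(
        {
            "time_s": trace.time,
            "ph": trace.ph,
            "o2_signal": trace.o2_signal,
            "ar_signal": trace.ar_signal,
            "light_umol_m2_s": trace.light,
            "temp_c": np.full(len(trace), trace.temperature - 273.15),
        }
    ).to_csv(path, index=False, float_format="%.10g")


def read_spectrum_csv(path, kind: str = "absorbance") -> Spectrum:
    """Load a wavelength_nm,value spectrum CSV."""
    df = pd.read_csv(path, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    for c in ("wavelength_nm", "value"):
        if c not in df.columns:
            raise SchemaError(f"spectrum file {path} missing column {c!r}")
    return Spectrum(
        df["wavelength_nm"].to_numpy(dtype=float),
        df["value"].to_numpy(dtype=float),
        kind=kind,
    )


def write_spectrum_csv(path, spectrum: Spectrum) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelength, "value": spectrum.value}
    ).to_csv(path, index=False, float_format="%.10g")


def read_titration_csv(
    path, sample_mass: float, acid_concentration: float
) -> cb.TitrationRecord:
    """Load a Gran titration CSV (acid_amount_g or acid_amount_mL, pH)."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if "ph" not in df.columns:
        raise SchemaError(f"titration file {path} missing column 'ph'")
    if "acid_amount_g" in df.columns:
        unit, col = "g", "acid_amount_g"
    elif "acid_amount_ml" in df.columns:
        unit, col = "mL", "acid_amount_ml"
    else:
        raise SchemaError(
            f"titration file {path} needs acid_amount_g or acid_amount_mL"
        )
    pts = tuple(
        (float(a), float(p)) for a, p in zip(df[col], df["ph"])
    )
    return cb.TitrationRecord(
        sample_mass=sample_mass,
        acid_concentration=acid_concentration,
        points=pts,
        amount_unit=unit,
    )


def write_fit_report(path, fit, extra: dict | None = None) -> None:
    """Serialize a P-vs-E fit as key: value text plus a point table."""
    lines = [
        f"gas: {fit.gas}",
        f"model: {fit.model}",
        f"P_max: {fit.P_max:.6g}",
        f"alpha: {fit.alpha:.6g}",
        f"beta: {fit.beta:.6g}",
        f"respiration_offset: {fit.respiration_offset:.6g}",
        f"se_P_max: {fit.se.get('P_max', float('nan')):.4g}",
        f"se_alpha: {fit.se.get('alpha', float('nan')):.4g}",
    ]
    for key, val in (extra or {}).items():
        lines.append(f"{key}: {val}")
    lines.append("")
    lines.append("light_umol_m2_s,rate,residual")
    pred = fit.predict(fit.light)
    for I, r, p in zip(fit.light, fit.rates, pred):
        lines.append(f"{I:g},{r:.6g},{r - p:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class RunConfig:
    """One processing run: paths, medium chemistry, sample and options.

    Built from a TOML file with [paths], [medium], [sample], [schedule],
    [options] and optional [o2_cal] sections; see :meth:`template` for a
    fully-commented default.
    """

    chemistry: cb.MediumChemistry
    chla: float
    od750: float = 0.0
    trace_path: Path | None = None
    absorbance_path: Path | None = None
    lamp_path: Path | None = None
    schedule: list[tuple[float, float]] | None = None
    constants: str = "lueker2000"
    trim_s: float = 10.0
    seed: int = 0
    dialect: str = "ph"
    o2_r_sat: float | None = None
    o2_r_zero: float | None = None
    output_dir: Path = Path("phoskit_out")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        raw = tomllib.loads(Path(path).read_text())
        med = raw.get("medium", {})
        try:
            chem = cb.MediumChemistry(
                salinity=med["salinity"],
                temperature=med["temperature_c"] + 273.15,
                total_alkalinity=med["total_alkalinity"],
                density=med.get("density", 1.0352),
                total_borate=med.get("total_borate"),
                total_phosphate=med.get("total_phosphate", 0.0),
                total_silicate=med.get("total_silicate", 0.0),
            )
        except KeyError as e:
            raise ConfigError(f"missing [medium] key {e}") from None
        sample = raw.get("sample", {})
        if "chla" not in sample:
            raise ConfigError("missing [sample] chla")
        opts = raw.get("options", {})
        paths = raw.get("paths", {})
        base = Path(path).parent

        def _p(key):
            v = paths.get(key)
            if v is None:
                return None
            p = (base / v).resolve()
            if not p.exists():
                raise ConfigError(f"configured path {key} = {v} does not exist")
            return p

        sched_raw = raw.get("schedule", {})
        schedule = None
        if sched_raw:
            levels = sched_raw.get("levels")
            period = sched_raw.get("period_s", 120.0)
            if levels is not None:
                from .simulate import protocol_schedule

                schedule = protocol_schedule(levels, period)
        o2 = raw.get("o2_cal", {})
        cfg = cls(
            chemistry=chem,
            chla=float(sample["chla"]),
            od750=float(sample.get("od750", 0.0)),
            trace_path=_p("trace"),
            absorbance_path=_p("absorbance"),
            lamp_path=_p("lamp"),
            schedule=schedule,
            constants=opts.get("constants", "lueker2000"),
            trim_s=float(opts.get("trim_s", 10.0)),
            seed=int(opts.get("seed", 0)),
            dialect=opts.get("dialect", "ph"),
            o2_r_sat=o2.get("r_sat"),
            o2_r_zero=o2.get("r_zero"),
            output_dir=Path(paths.get("output_dir", "phoskit_out")),
        )
        _check_od750(cfg.od750)
        return cfg

    @staticmethod
    def template() -> str:
        return (
            "# phoskit run configuration\n"
            "[paths]\n"
            "trace = \"trace.csv\"\n"
            "# absorbance = \"absorbance.csv\"\n"
            "# lamp = \"lamp.csv\"\n"
            "output_dir = \"phoskit_out\"\n\n"
            "[medium]\n"
            "salinity = 35.0\n"
            "temperature_c = 25.0\n"
            "total_alkalinity = 1980.1  # umol/kg\n"
            "density = 1.0352           # kg/L\n"
            "total_phosphate = 21.8     # umol/kg\n"
            "total_silicate = 105.6     # umol/kg\n\n"
            "[sample]\n"
            "chla = 2.0    # ug/mL\n"
            "od750 = 0.25  # 1/cm\n\n"
            "[schedule]\n"
            "levels = [0, 20, 50, 200, 500, 1000, 2000]\n"
            "period_s = 120\n\n"
            "[options]\n"
            "constants = \"lueker2000\"\n"
            "trim_s = 10.0\n"
            "seed = 0\n"
            "dialect = \"ph\"\n\n"
            "[o2_cal]\n"
            "r_sat = 10.0\n"
            "r_zero = 0.2\n"
        )
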