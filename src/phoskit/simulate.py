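"""Forward models: synthetic pHOS-MIMS traces, whole-cell absorbance spectra
and Gran titrations from known ground truth.

Every reduction stage in the package has a matching generator here, so the
whole pipeline can be exercised and its recovery error measured without
instrument data. The trace model runs the physics forward: a prescribed
P-vs-E truth drives DIC drawdown at constant total alkalinity, the carbonate
engine converts DIC back to pH, oxygen follows carbon through a fixed
photosynthetic quotient, and the gas channels are emitted through a linear
O2/Ar calibration truth. Noise is additive Gaussian on pH (electrode
counts) and multiplicative Gaussian on the ion-current channels (source/
pressure fluctuations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import carbonate as cb
from .calibration import OxygenCalibration, oxygen_saturation
from .errors import DomainError
from .photophys import Spectrum, platt
from .trace import OscillationTrace

__all__ = [
    "SimulationConfig",
    "protocol_schedule",
    "simulate_trace",
    "simulate_spectrum",
    "simulate_titration",
]

#: Protocol irradiance steps, umol quanta m-2 s-1.
PROTOCOL_LEVELS = (0.0, 20.0, 50.0, 200.0, 500.0, 1000.0, 2000.0)


def protocol_schedule(
    levels: Sequence[float] = PROTOCOL_LEVELS, period_s: float = 120.0
) -> list[tuple[float, float]]:
    """The alternating dark/light measurement schedule.

    The first dark period doubles as the light=0 measurement; each nonzero
    step is followed by a dark recovery period. Default: 2-min periods over
    the 0/20/50/200/500/1000/2000 steps (13 segments, 26 min).
    """
    sched: list[tuple[float, float]] = [(period_s, 0.0)]
    for lvl in levels:
        if lvl == 0.0:
            continue
        sched.append((period_s, float(lvl)))
        sched.append((period_s, 0.0))
    return sched


@dataclass
class SimulationConfig:
    """Ground truth for one synthetic incubation.

    P-vs-E truth per gas follows the offset convention: the net rate at
    irradiance I is platt(I; P_max, alpha, beta) - R, so the dark rate is -R.
    Oxygen is slaved to carbon through the constant photosynthetic quotient
    ``pq``. Noise: ``sigma_ph`` additive (pH units), ``sigma_signal``
    fractional multiplicative per gas channel.
    """

    chemistry: cb.MediumChemistry
    p_max: float = 154.79
    alpha: float = 1.11
    beta: float = 0.0
    respiration: float = 10.0
    pq: float = 1.2
    chla: float = 2.0  # ug mL-1
    od750: float = 0.25
    initial_ph: float = 8.05
    schedule: list[tuple[float, float]] = field(default_factory=protocol_schedule)
    sigma_ph: float = 5e-4
    sigma_signal: float = 0.0
    r_sat: float = 10.0
    r_zero: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_ph < 0 or self.sigma_signal < 0:
            raise DomainError("noise levels must be non-negative")
        if not self.schedule:
            raise DomainError("schedule must be nonempty")
        if not 7.5 <= self.initial_ph <= 8.5:
            raise DomainError("initial pH must lie in [7.5, 8.5]")

    def oxygen_calibration(self) -> OxygenCalibration:
        return OxygenCalibration(
            r_sat=self.r_sat,
            r_zero=self.r_zero,
            O2_sat=oxygen_saturation(
                self.chemistry.salinity, self.chemistry.temperature
            ),
        )


def _ph_lookup(chem: cb.MediumChemistry, k: cb.EquilibriumConstants):
    """Dense monotone DIC(pH) table for fast repeated pH-from-DIC inversion.

    A 1e-5 pH grid keeps the interpolation error below ~1e-8 pH, well under
    the electrode noise floor; endpoints outside the table raise through the
    scalar bisection solver instead.
    """
    grid = np.linspace(6.0, 10.0, 400_001)
    dic = cb.dic_from_ph(grid, chem, k).DIC
    # DIC decreases with pH; flip for np.interp's ascending requirement.
    return dic[::-1], grid[::-1]


def simulate_trace(cfg: SimulationConfig) -> OscillationTrace:
    """Generate one 1 Hz synthetic pHOS-MIMS trace.

    Euler integration at 1 s steps: the net carbon rate at the commanded
    light (dark -> -R) is drawn down from DIC, converted to pH at constant
    A_T through the carbonate engine; oxygen integrates PQ times the carbon
    rate from air saturation and is emitted as an O2/Ar signal pair through
    the linear calibration truth. Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    chem = cfg.chemistry
    k = cb.equilibrium_constants(chem)

    light = np.concatenate(
        [np.full(int(round(d)), lvl) for d, lvl in cfg.schedule]
    )
    n = len(light)
    time = np.arange(n, dtype=float)

    net_c = platt(light, cfg.p_max, cfg.alpha, cfg.beta) - cfg.respiration
    # umol mg-1 Chla h-1 -> umol kg-1 s-1 in the medium
    to_medium = cfg.chla / (chem.density * 3600.0)
    ddic = -net_c * to_medium
    do2 = cfg.pq * net_c * to_medium

    dic0 = cb.dic_from_ph(cfg.initial_ph, chem, k).DIC
    dic = dic0 + np.concatenate(([0.0], np.cumsum(ddic[:-1])))

    dic_tab, ph_tab = _ph_lookup(chem, k)
    if dic.min() < dic_tab[0] or dic.max() > dic_tab[-1]:
        raise DomainError(
            "simulated DIC drives pH outside [6, 10]; shorten the run or "
            "lower chla"
        )
    ph = np.interp(dic, dic_tab, ph_tab)

    o2cal = cfg.oxygen_calibration()
    o2 = o2cal.O2_sat + np.concatenate(([0.0], np.cumsum(do2[:-1])))
    r = cfg.r_zero + (o2 / o2cal.O2_sat) * (cfg.r_sat - cfg.r_zero)
    ar = np.ones(n)
    o2_signal = r * ar

    if cfg.sigma_ph > 0:
        ph = ph + rng.normal(0.0, cfg.sigma_ph, n)
    if cfg.sigma_signal > 0:
        o2_signal = o2_signal * (1.0 + rng.normal(0.0, cfg.sigma_signal, n))
        ar = ar * (1.0 + rng.normal(0.0, cfg.sigma_signal, n))

    return OscillationTrace(
        time=time,
        ph=ph,
        o2_signal=o2_signal,
        ar_signal=ar,
        light=light.astype(float),
        temperature=chem.temperature,
        chemistry=chem,
        chla=cfg.chla,
        od750=cfg.od750,
        ph_is_total=True,
    )


#: Pigment absorption bands of a diatom-like cell: (center nm, sigma nm,
#: weight m^2 mg-1 Chla). Chla Soret, carotenoid shoulder, Chla red peak.
_PIGMENT_BANDS = ((440.0, 22.0, 0.035), (490.0, 20.0, 0.018), (675.0, 10.0, 0.020))


def pigment_band_astar(wavelength: np.ndarray, weights=None) -> np.ndarray:
    """Gaussian-band model of a*_ph(lambda), m^2 mg-1 Chla."""
    w = [b[2] for b in _PIGMENT_BANDS] if weights is None else weights
    out = np.zeros_like(np.asarray(wavelength, dtype=float))
    for (c, s, _), wi in zip(_PIGMENT_BANDS, w):
        out = out + wi * np.exp(-0.5 * ((wavelength - c) / s) ** 2)
    return out


def simulate_spectrum(
    chla_mg_m3: float,
    packaging_factor: float = 1.0,
    seed: int = 0,
    path_m: float = 0.01,
) -> tuple[Spectrum, Spectrum]:
    """Synthetic whole-cell absorbance spectrum plus its generating a*_ph.

    A(lambda) = a*_ph(lambda) [Chla] x / ln(10), with a* the Gaussian pigment
    band sum scaled by the packaging factor (pigment self-shading inside the
    cell lowers the in-vivo specific absorption; 1 = no packaging). The seed
    jitters band weights by +-5% so replicate spectra differ realistically.
    Returns (absorbance spectrum, true a* spectrum).
    """
    if chla_mg_m3 <= 0:
        raise DomainError("chla must be positive")
    if not 0.0 < packaging_factor <= 1.0:
        raise DomainError("packaging_factor must be in (0, 1]")
    rng = np.random.default_rng(seed)
    wl = np.arange(400.0, 701.0, 1.0)
    weights = [b[2] * (1.0 + rng.uniform(-0.05, 0.05)) for b in _PIGMENT_BANDS]
    astar = packaging_factor * pigment_band_astar(wl, weights)
    absorbance = astar * chla_mg_m3 * path_m / np.log(10.0)
    return (
        Spectrum(wl, absorbance, kind="absorbance"),
        Spectrum(wl, astar, kind="a_star"),
    )


def simulate_titration(
    true_A_T: float,
    sample_mass: float = 50.0,
    acid_conc: float = 0.1723,
    n_points: int = 30,
    noise_ph: float = 0.0,
    seed: int = 0,
    chem: cb.MediumChemistry | None = None,
    initial_ph: float = 8.0,
    acid_span: float = 2.0,
    co2_retained: float = 0.02,
) -> cb.TitrationRecord:
    """Forward-model an open-cell Gran titration of a sample with known
    alkalinity.

    Cumulative acid additions span 5% to ``acid_span`` x the equivalence
    amount; at each step alkalinity and DIC are diluted by the added acid
    mass and pH follows from the full charge balance. Past the equivalence
    point the stirred open cell strips dissolved CO2, retaining the fraction
    ``co2_retained`` of the diluted DIC (residual CO2 is what limits Gran
    linearity). Gaussian pH noise is optional; reproducible per seed.

    ``sample_mass`` in g, ``acid_conc`` in mol kg-1 (gram-dialect record).
    """
    if true_A_T <= 0:
        raise DomainError("true_A_T must be positive")
    if chem is None:
        chem = cb.MediumChemistry(
            salinity=35.0, temperature=298.15, total_alkalinity=true_A_T
        )
    rng = np.random.default_rng(seed)
    k = cb.equilibrium_constants(chem)
    dic0 = cb.dic_from_ph(
        initial_ph,
        cb.MediumChemistry(
            chem.salinity,
            chem.temperature,
            true_A_T,
            chem.density,
            chem.total_borate,
            chem.total_phosphate,
            chem.total_silicate,
        ),
        k,
    ).DIC

    m0 = sample_mass
    m_eq = true_A_T * 1e-6 * m0 / acid_conc  # g of acid at equivalence
    acid_masses = np.linspace(0.05 * m_eq, acid_span * m_eq, n_points)

    points = []
    for ma in acid_masses:
        dil = m0 / (m0 + ma)
        alk = (true_A_T * m0 * 1e-3 - acid_conc * ma * 1000.0) / ((m0 + ma) * 1e-3)
        # alk now in umol kg-1 of the diluted mixture
        dic = dic0 * dil
        if alk < 0.0:
            dic = dic * co2_retained + 1e-9
        chem_d = cb.MediumChemistry(
            chem.salinity,
            chem.temperature,
            true_A_T,  # placeholder; the solver takes alkalinity explicitly
            chem.density,
            chem.total_borate * dil,
            chem.total_phosphate * dil,
            chem.total_silicate * dil,
        )
        ph = cb.ph_from_alkalinity_dic(alk, dic, chem_d, k)
        if noise_ph > 0:
            ph += rng.normal(0.0, noise_ph)
        points.append((float(ma), float(ph)))

    return cb.TitrationRecord(
        sample_mass=m0,
        acid_concentration=acid_conc,
        points=tuple(points),
        amount_unit="g",
    )
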