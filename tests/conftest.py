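import numpy as np
import pytest

from phoskit import carbonate as cb
from phoskit.simulate import SimulationConfig, simulate_trace


@pytest.fixture(scope="session")
def asw_chem() -> cb.MediumChemistry:
    """Artificial-seawater baseline: S=35, 25 C, measured A_T 1980.1 umol/kg,
    density 1.0352 kg/L, ESAW-like nutrient totals."""
    return cb.MediumChemistry(
        salinity=35.0,
        temperature=298.15,
        total_alkalinity=1980.1,
        density=1.0352,
        total_phosphate=21.8,
        total_silicate=105.6,
    )


@pytest.fixture(scope="session")
def constants(asw_chem) -> cb.EquilibriumConstants:
    return cb.equilibrium_constants(asw_chem)


@pytest.fixture(scope="session")
def noise_free_trace(asw_chem):
    """One zero-noise protocol trace with known P-vs-E truth."""
    cfg = SimulationConfig(chemistry=asw_chem, sigma_ph=0.0, sigma_signal=0.0, seed=1)
    return cfg, simulate_trace(cfg)
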