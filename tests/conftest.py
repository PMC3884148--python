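import warnings

import pytest

from co2perm.carbonate import CarbonateSystem
from co2perm.monolayer import monolayer_preset
from co2perm.o18 import CellSuspension

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def chamber_74():
    """Standard measuring-chamber chemistry (pH 7.40, 25 mM carbonate, 37C)."""
    return CarbonateSystem(pH=7.4)


@pytest.fixture(scope="session")
def chamber_73():
    """pH 7.3 solution, [HCO3-]/[CO2] ~ 17 — the Mills-Urey calibration point."""
    return CarbonateSystem(pH=7.3)


@pytest.fixture(scope="session")
def rbc_suspension():
    """Normal human red cells at the standard 0.02% chamber hematocrit."""
    return CellSuspension(cytocrit=0.0002, surface_to_volume_a=20000.0,
                          A_i=20000.0, pH_i=7.2, P_CO2=0.15, P_HCO3=1e-3,
                          P_H2O=5e-3)


@pytest.fixture(scope="session")
def mdck_suspension():
    """MDCK-type cells: A_i = 500, cytocrit chosen so cytocrit * A_i = 4."""
    return CellSuspension(cytocrit=0.008, surface_to_volume_a=2000.0,
                          A_i=500.0, pH_i=7.2, P_CO2=0.01, P_HCO3=1e-4,
                          P_H2O=2e-3)


@pytest.fixture(scope="session")
def monolayer_steady_states():
    """Steady states of the three canonical CA configurations (cached)."""
    return {name: monolayer_preset(name).steady_state()
            for name in ("curve1", "curve2", "curve3")}
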