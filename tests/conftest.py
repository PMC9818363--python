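import numpy as np
import pytest

from powderlife import EnvironmentSpec, IsothermFit, PackageSpec, PowderSpec
from powderlife import datasets


@pytest.fixture(scope="session")
def gab_fit():
    """A representative GAB isotherm (monolayer 0.05 kg/kg, C=10, k=0.8)."""
    return IsothermFit("GAB", {"Xm": 0.05, "C": 10.0, "k": 0.8})


@pytest.fixture(scope="session")
def printed_package():
    """Pouch constants of the bundled trial."""
    return PackageSpec(permeability_K=5.4e-8, area_Ap=0.0600)


@pytest.fixture(scope="session")
def ambient_env():
    return EnvironmentSpec(temperature_T=25.0, rel_humidity_Rh=0.60,
                           sat_pressure_pstar=3173.027)


@pytest.fixture(scope="session")
def accelerated_env():
    return EnvironmentSpec(temperature_T=40.0, rel_humidity_Rh=0.90,
                           sat_pressure_pstar=7380.726)


@pytest.fixture(scope="session")
def nominal_powder():
    return PowderSpec(dry_mass_Ws=0.0192, X_initial=0.004, X_critical=0.006)


@pytest.fixture(scope="session")
def trial():
    return datasets.load_storage_trial()


@pytest.fixture(scope="session")
def study():
    """Calibrated analysis of the bundled storage trial (cached)."""
    return datasets.reference_analysis()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
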