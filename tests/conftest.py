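import pytest

from mitotherm.bioenergetics import ThermogenicDrive
from mitotherm.thermal import MitochondrionSpec, ThermalEnvironment
from mitotherm.thermometry import CalibrationParams


@pytest.fixture
def canonical_drive():
    """The canonical working point: pmf 200 mV, UCP1 current 100 pA, eta 1."""
    return ThermogenicDrive(proton_current_pA=100.0, pmf_mV=200.0, efficiency=1.0)


@pytest.fixture
def unit_mito():
    """Spherical mitochondrion of 1 um^3 (radius ~0.6204 um)."""
    return MitochondrionSpec(volume_um3=1.0)


@pytest.fixture
def water_env():
    """Water-like cytosol: kappa 0.6 W/(m K), C 4.18e6 J/(K m^3)."""
    return ThermalEnvironment()


@pytest.fixture
def calibration():
    """Dye calibration at Tref 310 K, Ea 6.55 kcal/mol."""
    return CalibrationParams(reference_temperature_K=310.0)
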