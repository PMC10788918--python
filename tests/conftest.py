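import numpy as np
import pytest

from trastkit.photophysics import Excitation, IsomerizationModel, preset


@pytest.fixture
def cy5():
    return preset("cy5_free")


@pytest.fixture
def cy5_suv():
    return preset("cy5_suv")


@pytest.fixture
def cf640r():
    return preset("cf640r")


@pytest.fixture
def fcs_excitation():
    """Irradiance used in the FCS measurements: 16 kW/cm^2 at 640 nm."""
    return Excitation(irradiance=16e3, wavelength=640.0)


@pytest.fixture
def cy5_flow():
    """Free Cy5 with the thermal back-isomerization rate found in flow fits."""
    base = preset("cy5_free")
    return IsomerizationModel(
        sigma_n=base.sigma_n,
        sigma_biso=base.sigma_biso,
        k_iso=base.k_iso,
        k_biso_th=0.0016e6,
        k10=base.k10,
        name="cy5_flow",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
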