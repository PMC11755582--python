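import numpy as np
import pytest

from fasciatrack import ContractionScript, generate_video


@pytest.fixture(scope="session")
def adim_script():
    """Contraction script using the cohort-mean ADIM thicknesses."""
    return ContractionScript()


@pytest.fixture(scope="session")
def adim_video(adim_script):
    return generate_video(adim_script, seed=7)


@pytest.fixture()
def static_script():
    """No contraction, no drift, frozen speckle: every frame identical."""
    rest = {"OE": 5.22, "OI": 9.34, "TrA": 4.61}
    return ContractionScript(
        n_frames=25, rest_thickness=rest, contracted_thickness=dict(rest),
        ramp_up_start=5, hold_start=10, hold_end=15, ramp_down_end=20,
        static_speckle=True,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20250901)
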