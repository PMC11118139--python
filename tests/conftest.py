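import numpy as np
import pytest
from hypothesis import HealthCheck, settings as hypothesis_settings

from electrorupture import (
    CellElectricalModel,
    FieldModel,
    MediumProperties,
    PhysicalContext,
    RampProtocol,
)
from electrorupture.config import default_settings
from electrorupture.pipeline import run_synthetic_condition

hypothesis_settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
hypothesis_settings.load_profile("default")


@pytest.fixture(scope="session")
def run_settings():
    return default_settings()


@pytest.fixture(scope="session")
def medium():
    return MediumProperties()


@pytest.fixture(scope="session")
def cell():
    """Representative cell: 10 µm radius, 20 kHz crossover."""
    return CellElectricalModel(radius_m=10e-6, crossover_hz=20e3, cell_id="c0")


@pytest.fixture(scope="session")
def field_model():
    return FieldModel()


@pytest.fixture(scope="session")
def physics():
    return PhysicalContext()


@pytest.fixture(scope="session")
def ramp():
    return RampProtocol(rate_vpp_per_s=0.05)


@pytest.fixture(scope="session")
def condition_fits():
    """Full synthetic recovery for the three cholesterol conditions.

    Pore radii at the three reported condition values; the untreated and
    2.5 mM analogues use k0 = 1e-13 s^-1, the 5 mM analogue a modal-voltage
    calibrated k0 (its most probable rupture tension would otherwise exceed
    what the 2-10 V_pp ramp can deliver).  500 cells per loading rate, events
    recovered from synthesized brightness traces through the detector.
    """
    spec = [
        ("untreated", 1.07e-9, 1e-13, 11),
        ("mbcd_2p5mM", 0.80e-9, 1e-13, 12),
        ("mbcd_5mM", 0.58e-9, None, 13),
    ]
    return [
        run_synthetic_condition(
            radius, k0, n_cells_per_rate=500, seed=seed, condition=name
        )
        for name, radius, k0, seed in spec
    ]


@pytest.fixture(scope="session")
def ordering_fits():
    """Three conditions whose generated Bell slopes sit in exact ratio 1:2:4.

    Slope = kBT/(pi r^2), so radii r0, r0/sqrt(2), r0/2 generate slopes
    1:2:4.  Each condition's k0 is calibrated so rupture stays inside the
    voltage window (k0 rises as the pore shrinks, so the generating barrier
    W0 = ln(v0/k0) falls along the series, as cholesterol depletion would).
    """
    r0 = 1.07e-9
    radii = [r0, r0 / np.sqrt(2.0), r0 / 2.0]
    return [
        run_synthetic_condition(
            r, None, n_cells_per_rate=300, seed=20 + i,
            condition=f"slope_x{2**i}", detect=False,
        )
        for i, r in enumerate(radii)
    ]
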