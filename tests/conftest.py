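import pytest
from hypothesis import HealthCheck, settings

from nadflux import CalibrationStandard, CellContext, KineticParams

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def exact_standards():
    """Standards lying exactly on area = 100 * amount."""
    return [
        CalibrationStandard("d3-NAD+", 0.0, 0.0),
        CalibrationStandard("d3-NAD+", 1.0, 100.0),
        CalibrationStandard("d3-NAD+", 2.0, 200.0),
        CalibrationStandard("d3-NAD+", 5.0, 500.0),
    ]


@pytest.fixture
def hepg2_context():
    """Cell context of the reference HepG2 labeling run."""
    return CellContext(
        cell_count=4.04e5,
        cell_volume_pl=2.5,
        medium_volume_ml=1.0,
        d4_nam_conc_um=2.0,
    )


@pytest.fixture
def default_params():
    return KineticParams()
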