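import warnings

import pytest

from sovt.geometry import build_model_airway
from sovt.simulate import SimConfig, simulate

# tube geometries outside the empirical fit range warn; tests exercise them
# deliberately
warnings.filterwarnings("ignore", message=".*calibration range.*")


@pytest.fixture(scope="session")
def model_airway():
    """Reference model airway without the lip tube."""
    return build_model_airway(tube=None)


@pytest.fixture(scope="session")
def results_run(model_airway):
    """The semi-occluded reference run: 2.5 kPa, 3 mm x 10 cm tube, pitch
    scale 300/130, 1 s of simulated time."""
    return simulate(model_airway, SimConfig(duration_s=1.0))


@pytest.fixture(scope="session")
def open_run(model_airway):
    """Open-mouth phonation (no tube) at the same lung pressure."""
    return simulate(model_airway, SimConfig(duration_s=0.8, tube=None))


@pytest.fixture(scope="session")
def expansion_runs():
    """Expansion experiment across lip-tube diameters (short runs)."""
    from sovt.experiments import run_expansion_experiment
    return run_expansion_experiment(duration_s=0.5)


@pytest.fixture(scope="session")
def epilarynx_control():
    """Free vs stiffened epilarynx paired runs (short)."""
    from sovt.experiments import run_epilarynx_control_experiment
    return run_epilarynx_control_experiment(duration_s=0.6)


@pytest.fixture(scope="session")
def inertagram_experiment():
    from sovt.experiments import run_inertagram_experiment
    return run_inertagram_experiment()
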