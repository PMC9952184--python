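import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vancosim as vs

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def typical_patient() -> vs.Patient:
    """A patient near the reference cohort's covariate means."""
    return vs.Patient(id="p-typ", sex="M", age=53.67, tbw=68.87, scr=0.76)


@pytest.fixture
def q12h_regimen() -> vs.DosingRegimen:
    """1000 mg loading then 1000 mg q12h over 1 h, 48 h horizon."""
    return vs.DosingRegimen(
        loading_dose=1000.0, maintenance_dose=1000.0, interval=12.0,
        infusion_duration=1.0, horizon=48.0,
    )


@pytest.fixture
def two_cpt_params() -> vs.PKParameters:
    return vs.PKParameters(cl=4.5, vc=58.4, vp=38.4, q=6.5)


@pytest.fixture
def one_cpt_params() -> vs.PKParameters:
    return vs.PKParameters(cl=4.0, vc=50.0)


def random_params(rng: np.random.Generator, two_compartment: bool) -> vs.PKParameters:
    """Physiologically plausible random parameter draw for sweeps."""
    cl = rng.uniform(0.5, 12.0)
    vc = rng.uniform(15.0, 120.0)
    if not two_compartment:
        return vs.PKParameters(cl=cl, vc=vc)
    return vs.PKParameters(cl=cl, vc=vc, vp=rng.uniform(20.0, 150.0), q=rng.uniform(2.0, 15.0))


def random_regimen(rng: np.random.Generator) -> vs.DosingRegimen:
    interval = rng.uniform(6.0, 24.0)
    return vs.DosingRegimen(
        loading_dose=rng.uniform(0.0, 2500.0),
        maintenance_dose=rng.uniform(250.0, 2000.0),
        interval=interval,
        infusion_duration=rng.uniform(0.5, min(4.0, interval)),
        horizon=96.0,
    )
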