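import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from sprkinetics import (
    BindingComponent,
    InjectionSchedule,
    KineticModel,
)


@pytest.fixture
def one_site_model():
    return KineticModel((BindingComponent(ka=1e5, kd=1e-3, rmax=50.0),))


@pytest.fixture
def two_site_model():
    """Well-separated two-component model (kd differs 30x)."""
    return KineticModel(
        (
            BindingComponent(ka=1e5, kd=1e-3, rmax=30.0),
            BindingComponent(ka=2e5, kd=3e-2, rmax=60.0),
        )
    )


@pytest.fixture
def full_schedule():
    return InjectionSchedule.full_kinetics(1e-7, 120.0, 300.0)


@pytest.fixture
def single_cycle_schedule():
    concs = [1e-8, 3e-8, 1e-7, 3e-7, 1e-6]
    return InjectionSchedule.single_cycle(concs, 60.0, 600.0)


@pytest.fixture
def t_grid(full_schedule):
    return np.arange(full_schedule.start_s, full_schedule.end_s, 0.1)
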