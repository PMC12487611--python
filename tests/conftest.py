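"""Shared fixtures: the synthetic surrogate cell and its simulated protocols.

Expensive simulations (the wild-type F-I family and the NaChBac
depolarization-block trace) are session-scoped so the protocol, solver
and acceptance tests reuse one run.
"""

import numpy as np
import pytest

from kcmodel import channels as ch
from kcmodel.morphology import PassiveParams
from kcmodel.simulator import (CompartmentalModel, ElectrodeSpec,
                               current_step_protocol)
from kcmodel.synth import default_morphology

FI_STEPS = (-20, 10, 20, 30, 60, 100)


@pytest.fixture(scope="session")
def morph():
    return default_morphology(seed=0)


@pytest.fixture(scope="session")
def passive():
    return PassiveParams()


@pytest.fixture(scope="session")
def presets():
    return ch.presets()


@pytest.fixture(scope="session")
def wt_model(morph, passive, presets):
    return CompartmentalModel.from_morphology(
        morph, passive, presets["WT*"], electrode=ElectrodeSpec())


@pytest.fixture(scope="session")
def nachbac_model(morph, passive, presets):
    return CompartmentalModel.from_morphology(
        morph, passive, presets["NaChBac*"], electrode=ElectrodeSpec())


@pytest.fixture(scope="session")
def wt_fi_protocol():
    return current_step_protocol(steps=FI_STEPS, V0=-60.0)


@pytest.fixture(scope="session")
def wt_traces(wt_model, wt_fi_protocol):
    return wt_model.run_current_clamp(wt_fi_protocol)


@pytest.fixture(scope="session")
def nachbac_trace_20pa(nachbac_model):
    proto = current_step_protocol(steps=(20,), V0=-69.0)
    return nachbac_model.run_current_clamp(proto)[0]


@pytest.fixture(scope="session")
def wt_trace_20pa(wt_model):
    proto = current_step_protocol(steps=(20,), V0=-60.0)
    return wt_model.run_current_clamp(proto)[0]
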