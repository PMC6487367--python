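"""Shared fixtures.

The expensive whole-model simulations are session-scoped and shared by
several tests; everything is deterministic, so sharing records does not
couple test outcomes.
"""

import numpy as np
import pytest

import hexawalk as hw
from hexawalk.control import ModeCommand, Schedule
from hexawalk.params import ModelParams, SimulationConfig


#: the canonical behavioral pipeline: bilateral-sync start, transition
#: to tripod, then to (B-type) tetrapod, then back to tripod
PIPELINE_CMDS = [("set_gait", 3000.0, "tripod"),
                 ("set_gait", 7600.0, "tetrapod"),
                 ("set_gait", 12300.0, "tripod")]


@pytest.fixture(scope="session")
def pipeline_record():
    asm = hw.assemble()
    cmds = [ModeCommand(k, t, gait=g) for k, t, g in PIPELINE_CMDS]
    return hw.run(asm, Schedule(cmds, initial_gait="tetrapod"),
                  SimulationConfig(t_end=18000))


@pytest.fixture(scope="session")
def pipeline_swings(pipeline_record):
    return hw.extract_all(pipeline_record)


@pytest.fixture(scope="session")
def single_leg_tetrapod():
    return hw.simulate_single_leg(duration=10000, gait="tetrapod")


@pytest.fixture(scope="session")
def single_leg_tripod():
    return hw.simulate_single_leg(duration=10000, gait="tripod")


@pytest.fixture(scope="session")
def cpg_tetrapod():
    return hw.simulate_cpg((0.20, 0.295), duration=12000)
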