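"""Shared fixtures.

The expensive simulations (the full dose-response sweep, the timing
protocol, and a pair of fully-recorded 80 Hz runs) are session-scoped so
the acceptance and property tests share one execution each.
"""

import numpy as np
import pytest

import rgc_mg as rm
from rgc_mg.protocols import run_frequency_row


@pytest.fixture(scope="session")
def params():
    return rm.ModelParameters()


@pytest.fixture(scope="session")
def kin():
    return rm.default_kinetics()


@pytest.fixture(scope="session")
def sweep():
    """Full default dose-response sweep (6 frequencies x 24 Mg values)."""
    return rm.run_dose_response()


@pytest.fixture(scope="session")
def timing_table():
    """Default intervention-timing experiment."""
    return rm.run_timing_experiment()


@pytest.fixture(scope="session")
def mech_pair():
    """Fully recorded 80 Hz runs at 0.2 and 1.8 mM Mg2+ (for mechanistic metrics)."""
    return run_frequency_row(80.0, [0.2, 1.8], record=("V", "Ca", "sAMPA", "sNMDA"))


@pytest.fixture(scope="session")
def quiet_trace(params, kin):
    """3 s simulation with no glutamate input, full state recording."""
    proto = rm.StimulusProtocol(
        pulse_freq=10.0, pulse_amp=0.0, stim_start=0.0, stim_end=3000.0, t_end=3000.0,
        mg_schedule=((0.0, 1.0),),
    )
    return rm.simulate_protocol(proto, params, kin, record=rm.model.STATE_NAMES)


@pytest.fixture(scope="session")
def short_80hz_trace(params, kin):
    """600 ms 80 Hz / 0.2 mM run with every state variable recorded."""
    proto = rm.StimulusProtocol(
        pulse_freq=80.0, stim_start=0.0, stim_end=600.0, t_end=600.0, mg_schedule=((0.0, 0.2),)
    )
    return rm.simulate_protocol(proto, params, kin, record=rm.model.STATE_NAMES)
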