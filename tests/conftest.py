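"""Shared fixtures: canonical parameter sets, portraits, scenario runs.

Expensive artefacts (scenario runs, quasi-potential surfaces, the symmetric
parameter sweep) are session-scoped so every test file reuses one
computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from togglescape import (compute_portrait, integrate, make_scenario)
from togglescape.events import classify
from togglescape.scenarios import (A_C_PITCHFORK, A_C_SADDLE_NODE, BASELINE,
                                   SCENARIO_NAMES)

#: representative a=c values safely inside each regime of the packaged sweep
A_BISTABLE = 0.30
A_TRISTABLE = 0.70
A_MONOSTABLE = 0.90


@pytest.fixture(scope="session")
def baseline():
    return BASELINE


@pytest.fixture(scope="session")
def bistable_params():
    return BASELINE.replace(a=A_BISTABLE, c=A_BISTABLE)


@pytest.fixture(scope="session")
def tristable_params():
    return BASELINE.replace(a=A_TRISTABLE, c=A_TRISTABLE)


@pytest.fixture(scope="session")
def monostable_params():
    return BASELINE.replace(a=A_MONOSTABLE, c=A_MONOSTABLE)


@pytest.fixture(scope="session")
def bistable_portrait(bistable_params):
    return compute_portrait(bistable_params)


@pytest.fixture(scope="session")
def tristable_portrait(tristable_params):
    return compute_portrait(tristable_params)


@pytest.fixture(scope="session")
def monostable_portrait(monostable_params):
    return compute_portrait(monostable_params)


@pytest.fixture(scope="session")
def sweep_values():
    """a=c grid spanning all three regimes, avoiding the exact boundaries."""
    return np.linspace(0.30, 0.90, 25)


@pytest.fixture(scope="session")
def sweep_portraits(sweep_values):
    return [
        compute_portrait(BASELINE.replace(a=float(a), c=float(a)),
                         with_separatrices=False)
        for a in sweep_values
    ]


@pytest.fixture(scope="session")
def scenario_runs():
    """All five canonical scenarios, run and classified once."""
    out = {}
    for name in SCENARIO_NAMES:
        sc = make_scenario(name)
        res = integrate(sc.schedule, sc.s0)
        events, notes = classify(res)
        out[name] = (sc, res, events, notes)
    return out


@pytest.fixture(scope="session")
def pitchfork_values():
    return A_C_PITCHFORK


@pytest.fixture(scope="session")
def saddle_node_value():
    return A_C_SADDLE_NODE
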