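"""Shared fixtures: the published parameter set and the expensive branch traces.

Branch continuations and multistart equilibrium searches are session-scoped
so each is computed once for the whole suite.
"""

import numpy as np
import pytest

from gutswitch import find_fixed_points, preset, trace_branch

#: equilibrium states reported for the bistable operating point k_Bo = 130
INFLAMED_STATE = np.array([0.178369, 1.783690, 20.365623, 0.347144, 6.079745])
NON_INFLAMED_STATE = np.array(
    [0.00002003, 0.00020025, 0.09248014, 0.00660570, 50.382992]
)


@pytest.fixture(scope="session")
def params():
    return preset("fig2a")


@pytest.fixture(scope="session")
def core_fixed_points(params):
    """All equilibria of the core model at k_Bo = 130, sorted by B."""
    return find_fixed_points(params, "core")


@pytest.fixture(scope="session")
def core_branch(params):
    """Lumen-butyrate hysteresis branch of the core model."""
    return trace_branch(params, "core", "k_Bo", (10.0, 300.0))


@pytest.fixture(scope="session")
def extended_branch(params):
    return trace_branch(params, "extended", "k_Bo", (10.0, 300.0))


@pytest.fixture(scope="session")
def kbl_branch(params):
    """Lumen-LPS branch of the core model at k_Bo = 130."""
    return trace_branch(params, "core", "k_bl", (0.0, 50.0))


@pytest.fixture(scope="session")
def stable_pair(core_fixed_points):
    """(inflamed, non-inflamed) stable equilibria at k_Bo = 130."""
    stable = [fp for fp in core_fixed_points if fp.stability == "stable"]
    return stable[0], stable[-1]
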