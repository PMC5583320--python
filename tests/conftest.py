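"""Shared fixtures: calibrated presets and cached reference sessions."""

from dataclasses import replace

import pytest

import pbutkin as pk
from pbutkin import presets


@pytest.fixture(scope="session")
def albumin():
    return presets.DEFAULT_ALBUMIN


@pytest.fixture(scope="session")
def geometry():
    return pk.dialyzer_preset("F180NR")


@pytest.fixture(scope="session")
def session_cfg():
    """Standard 4-h session on a moderate grid for property tests."""
    return replace(presets.DEFAULT_SESSION, n_x=40)


@pytest.fixture(scope="session")
def fine_session_cfg():
    """Production-resolution session used for quantitative comparisons."""
    return replace(presets.DEFAULT_SESSION, n_x=100)


def run_calibrated_session(name, cfg, K_ic_T=None, binding_degree=None):
    sp = presets.calibrated_species(name, binding_degree)
    params = presets.calibrated_parameters(name, binding_degree=binding_degree,
                                           K_ic_T=K_ic_T)
    state0 = presets.calibrated_patient_state(name, binding_degree=binding_degree)
    geom = pk.dialyzer_preset("F180NR")
    return pk.simulate_session(state0, params, sp, geom, cfg)


@pytest.fixture(scope="session")
def pcg_session(session_cfg):
    return run_calibrated_session("pCG", session_cfg)


@pytest.fixture(scope="session")
def is_session(session_cfg):
    return run_calibrated_session("IS", session_cfg)


@pytest.fixture(scope="session")
def pbut_sessions(session_cfg, pcg_session, is_session):
    """All four calibrated PBUT sessions keyed by toxin name."""
    out = {"pCG": pcg_session, "IS": is_session}
    for name in ("IAA", "pCS"):
        out[name] = run_calibrated_session(name, session_cfg)
    return out
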