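"""Shared fixtures: compact synthetic sessions reused across test modules."""

import numpy as np
import pytest

from lidpipe import synth

FS = 2000.0


@pytest.fixture(scope="session")
def coupled_session():
    """120-s session: M1+dStr share an 80-Hz NBG at kappa=8; thal independent."""
    osc = synth.OscillationSpec("nbg", 80.0, 10.0, amplitude=50.0,
                                structures=("M1", "dStr"), schedule=(),
                                kappa=8.0)
    cfg = synth.SessionConfig(duration_s=120.0,
                              structures=("M1", "dStr", "thal"),
                              wires_per_structure=2, oscillations=(osc,),
                              seed=101)
    rec, truth = synth.generate_session(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def gated_session():
    """240-s session with the NBG on only during 60-180 s (4 wires, 1 structure)."""
    osc = synth.OscillationSpec("nbg", 80.0, 10.0, amplitude=50.0,
                                structures=("M1",), schedule=((60.0, 180.0),),
                                kappa=8.0)
    cfg = synth.SessionConfig(duration_s=240.0, structures=("M1",),
                              wires_per_structure=4, oscillations=(osc,),
                              seed=202)
    rec, truth = synth.generate_session(cfg)
    return cfg, rec, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
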