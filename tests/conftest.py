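"""Shared fixtures: the calibrated baseline circuit and steady-state
runs of the four study conditions (computed once per session)."""

import pytest

from atriasim.engine import simulate
from atriasim.presets import baseline_sinus
from atriasim.scenarios import apply_laao, make_af, make_flutter


@pytest.fixture(scope="session")
def baseline():
    return baseline_sinus()


@pytest.fixture(scope="session")
def baseline_run(baseline):
    return simulate(baseline, 30.0)


@pytest.fixture(scope="session")
def laao_run(baseline):
    return simulate(apply_laao(baseline), 30.0)


@pytest.fixture(scope="session")
def flutter_run(baseline):
    return simulate(make_flutter(baseline, 150.0), 30.0)


@pytest.fixture(scope="session")
def af_run(baseline):
    return simulate(make_af(baseline), 30.0)
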