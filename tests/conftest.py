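"""Shared fixtures: expensive steady states computed once per session."""

import pytest

from c4sim import Drivers, Variant, build_model, run_to_steady_state


@pytest.fixture(scope="session")
def std_model():
    return build_model(Variant.NADP_ME_STANDARD)


@pytest.fixture(scope="session")
def std_2000(std_model):
    return run_to_steady_state(std_model, Drivers(ppfd=2000.0))


@pytest.fixture(scope="session")
def std_1500(std_model):
    return run_to_steady_state(std_model, Drivers(ppfd=1500.0))


@pytest.fixture(scope="session")
def mixed_2000():
    model = build_model(Variant.ASP_MAL_PEPCK_ME)
    return run_to_steady_state(model, Drivers(ppfd=2000.0))
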