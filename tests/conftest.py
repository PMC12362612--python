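"""Shared fixtures: nominal model specs and cached equilibrium sets."""

import numpy as np
import pytest

import fatebias as fb


@pytest.fixture(scope="session")
def nominal():
    return fb.nominal_params()


@pytest.fixture(scope="session")
def toggle(nominal):
    return fb.make_toggle(nominal)


@pytest.fixture(scope="session")
def controlled_neg(nominal):
    """Controlled toggle, negative-feedback architecture (senses target Y1)."""
    return fb.make_controlled_toggle(nominal, fb.ControllerConfig(sense_species="Y1"))


@pytest.fixture(scope="session")
def controlled_pos(nominal):
    """Controlled toggle, positive-feedback architecture (senses Y2)."""
    return fb.make_controlled_toggle(nominal, fb.ControllerConfig(sense_species="Y2"))


@pytest.fixture(scope="session")
def mutual_activation(nominal):
    return fb.make_mutual_activation(nominal)


@pytest.fixture(scope="session")
def tristable_base():
    return fb.make_toggle_selfactivation(fb.tristable_params(), double=True)


@pytest.fixture(scope="session")
def toggle_eqs(toggle):
    return fb.find_equilibria(toggle)


@pytest.fixture(scope="session")
def toggle_attractors(toggle_eqs):
    """Y1-high and Y2-high stable locations of the nominal toggle."""
    return {("Y1-high" if e.y[0] > e.y[1] else "Y2-high"): e.y
            for e in toggle_eqs.stable}
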