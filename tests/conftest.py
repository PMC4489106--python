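import numpy as np
import pytest

from fishposture.eigenshape import decompose, project
from fishposture.neuro import simulate_bout
from fishposture.synthetic import (
    EnsembleSpec,
    generate_ensemble,
    rest_params,
    scoot_params,
    turn_params,
)


@pytest.fixture(scope="session")
def scoot_bout():
    return simulate_bout(scoot_params(), duration_ms=280, bout_id="scoot")


@pytest.fixture(scope="session")
def turn_bout():
    return simulate_bout(turn_params(), duration_ms=280, bout_id="turn")


@pytest.fixture(scope="session")
def rest_bout():
    return simulate_bout(rest_params(), duration_ms=280, bout_id="rest")


@pytest.fixture(scope="session")
def small_ensemble():
    """A 40-bout mixed ensemble at the default study conditions."""
    return generate_ensemble(EnsembleSpec(n_scoot=21, n_turn=14, n_rest=5, seed=1))


@pytest.fixture(scope="session")
def collective_basis(small_ensemble):
    basis, trajs = decompose([r.spine for r in small_ensemble])
    return basis, trajs


@pytest.fixture(scope="session")
def archetype_trajs(collective_basis, scoot_bout, turn_bout):
    basis, _ = collective_basis
    return {
        "scoot": project(scoot_bout, basis, k_max=3),
        "turn": project(turn_bout, basis, k_max=3),
    }
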