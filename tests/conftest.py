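from datetime import datetime

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from smstailor.engine import GroupWeights, SelectionState
from smstailor.interaction import ParticipantState
from smstailor.library import BCTGroup, Message, MessageLibrary, generate_fixture_library


@pytest.fixture(scope="session")
def pilot_lib():
    return generate_fixture_library("pilot", seed=7)


@pytest.fixture(scope="session")
def feas_lib():
    return generate_fixture_library("feasibility", seed=7)


def make_tiny_library(n_groups=3, per_group=2, n_lifestyle=2, q=2, study="feasibility"):
    """A hand-sized pool for exhaustive engine checks."""
    groups = []
    for i in range(1, n_groups + 1):
        gid = f"g{i}"
        groups.append(
            BCTGroup(
                group_id=gid,
                label=f"Group {i}",
                members=[
                    Message(f"{gid}-m{k}", f"bct text {gid}/{k}", "bct", gid)
                    for k in range(1, per_group + 1)
                ],
            )
        )
    lifestyle = [
        Message(f"life-{k}", f"lifestyle text {k}", "lifestyle")
        for k in range(1, n_lifestyle + 1)
    ]
    return MessageLibrary(
        study=study, groups=groups, lifestyle=lifestyle, control=[], interleave_q=q
    )


@pytest.fixture
def tiny_lib():
    return make_tiny_library()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fresh_state():
    return SelectionState()


@pytest.fixture
def active_participant():
    return ParticipantState(
        participant_id="p0001",
        study="feasibility",
        arm="intervention",
        status="active",
        delivery_window="AM",
        started_at=datetime(2024, 1, 8, 9, 0),
    )


def uniform_weights(lib):
    return GroupWeights.uniform(lib)
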