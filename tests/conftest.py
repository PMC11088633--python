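"""Shared fixtures: small deterministic populations and kinematic suites."""

import numpy as np
import pytest

from reafference import synth


@pytest.fixture(scope="session")
def small_population():
    return synth.sample_population(40, seed=101)


@pytest.fixture(scope="session")
def transient_suite():
    """Ten-trial kinematic suite for the transient conditions."""
    return synth.condition_suite(
        ("head_on_body_passive", "head_on_body_active", "attempted"),
        10, seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def downsample_kin(k, step):
    return synth.KinematicTrace(
        t=k.t[::step], head_pos=k.head_pos[::step],
        head_vel=k.head_vel[::step], head_acc=k.head_acc[::step],
        body_pos=k.body_pos[::step], body_vel=k.body_vel[::step],
        body_acc=k.body_acc[::step],
        passive_head_vel=k.passive_head_vel[::step],
        active_head_vel=k.active_head_vel[::step])
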