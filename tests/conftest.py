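"""Shared fixtures: small synthetic sessions built at test time."""

import numpy as np
import pytest

from dendroglu.detection import run_period_mask
from dendroglu.session import BehaviorSession
from dendroglu.simulate import GeneratorParams, generate_behavior, generate_session


@pytest.fixture(scope="session")
def small_params():
    return GeneratorParams(duration_s=240, n_cells=4, branches_per_cell=1,
                           rois_per_branch=18)


@pytest.fixture(scope="session")
def behavior(small_params):
    return generate_behavior(small_params, seed=11)


@pytest.fixture(scope="session")
def small_session(small_params):
    """(behavior, combined traces, truth) for a 4-cell 4-min session."""
    return generate_session(small_params, seed=5)


def constant_speed_behavior(speed=20.0, duration_s=300.0, fps=30.0,
                            track_length=300.0, teleport_delay_s=1.0):
    """Deterministic sawtooth running at constant speed with teleports."""
    n = int(duration_s * fps)
    dt = 1.0 / fps
    pos = np.zeros(n)
    vel = np.zeros(n)
    trav = np.zeros(n, dtype=int)
    p, t_id, hold = 0.0, 0, 0.0
    for i in range(n):
        if hold > 0:
            hold -= dt
            if hold <= 0:
                p, t_id = 0.0, t_id + 1
        else:
            vel[i] = speed
            p += speed * dt
            if p >= track_length:
                p = track_length
                hold = teleport_delay_s
        pos[i] = p
        trav[i] = t_id
    beh = BehaviorSession(
        time=np.arange(n) * dt, position=pos, velocity=vel,
        traversal_id=trav, run_mask=np.zeros(n, dtype=bool),
        track_length=track_length,
    )
    beh.run_mask = run_period_mask(beh)
    return beh


@pytest.fixture(scope="session")
def sawtooth_behavior():
    return constant_speed_behavior()
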