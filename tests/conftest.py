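import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import motionscore as ms

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_params():
    """Noise- and jitter-free abduction movement parameters."""
    return ms.default_movement_params(
        "abduction", noise_sd_deg=0.0, duration_jitter=0.0,
        peak_jitter=0.0, tremor_amplitude_deg=0.0, participant_sd_deg=0.0)


@pytest.fixture
def small_dataset():
    """A reduced protocol: 2 participants, all exercises, 4 reps/round."""
    plan = ms.ProtocolPlan(n_participants=2, reps_per_round=4)
    return ms.generate_protocol_dataset(plan, seed=11)


def make_segments(n, rng, exercise="abduction", condition="normal",
                  reps_per_clip=None, **param_overrides):
    """Segments from one synthetic clip (convenience for module tests)."""
    from motionscore.evaluation import segment_dataset
    from motionscore.synth import ClipRecord, generate_clip_set

    params = ms.default_movement_params(exercise, **param_overrides)
    reps = reps_per_clip or n
    clips = []
    made = 0
    pid = 0
    while made < n:
        take = min(reps, n - made)
        trajs = generate_clip_set(params, condition, exercise, take, rng)
        clips.append(ClipRecord(participant=pid, exercise=exercise,
                                side="left", condition=condition,
                                round_index=0, trajectories=trajs))
        made += take
        pid += 1
    records = segment_dataset(clips)
    return [r.segment for r in records]
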