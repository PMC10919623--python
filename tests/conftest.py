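import numpy as np
import pytest

import wearsite as ws
from wearsite.windowing import LabeledWindowSet


@pytest.fixture(scope="session")
def adult_profile():
    return ws.ParticipantProfile(id="A1", group="adult", sex="female",
                                 age=27.0, height=170.0, weight=63.0,
                                 resting_vo2=4.09)


@pytest.fixture(scope="session")
def child_profile():
    return ws.ParticipantProfile(id="C1", group="child", sex="male",
                                 age=12.0, height=150.0, weight=41.0,
                                 resting_vo2=5.71)


@pytest.fixture(scope="session")
def small_cohort():
    """2 adults + 2 children with full three-site sessions and ground truth."""
    profiles = ws.sample_participants(2, 2, seed=42)
    sessions, results = {}, {}
    for i, p in enumerate(profiles):
        protocol = ws.draw_protocol(p, seed=1000 + i)
        s = ws.simulate_session(p, protocol, ("hip", "wrist", "chest"),
                                seed=2000 + i)
        sessions[p.id] = s
        results[p.id] = ws.session_ground_truth(s)
    return profiles, sessions, results


@pytest.fixture(scope="session")
def cohort_windows(small_cohort):
    """Hip+wrist windows for the small cohort, labeled via the pipeline."""
    profiles, sessions, results = small_cohort
    sets = []
    for p in profiles:
        _, bres = results[p.id]
        for site in ("hip", "wrist"):
            sets.append(ws.segment(sessions[p.id].recordings[site], bres, p))
    return profiles, LabeledWindowSet.concatenate(sets)


def toy_window_set(n=500, seed=0, separation=0.5):
    """Windows whose site label equals the sign of the channel-0 mean."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 100, 3)).astype(np.float32)
    is_hip = rng.random(n) < 0.5
    x[:, :, 0] += np.where(is_hip, separation, -separation)[:, None]
    return LabeledWindowSet(
        windows=x,
        site=np.where(is_hip, "hip", "wrist").astype(object),
        intensity=np.where(is_hip, "light", "moderate").astype(object),
        participant_id=np.full(n, "P1", dtype=object),
        group=np.full(n, "adult", dtype=object))
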