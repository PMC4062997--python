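import numpy as np
import pytest

from behavtrace import synthdata as sd


@pytest.fixture
def small_scene():
    """Compact scene that keeps rendering and flow computation fast."""
    return sd.SceneSpec(frame_size=(64, 64), fps=25.0, actor_size=(18, 28),
                        actor_start=(32.0, 40.0))


@pytest.fixture
def walk_scene():
    """Wide scene leaving room for multi-second horizontal walks."""
    return sd.SceneSpec(frame_size=(160, 64), fps=25.0, actor_size=(18, 28),
                        actor_start=(40.0, 36.0))


@pytest.fixture
def walk_right_script():
    """3 s rightward reach at 2 px per OF pair (2/3 px per frame)."""
    seg = sd.Segment("3a", 0.0, 3.0, direction_deg=0.0, speed=50.0 / 3.0)
    return sd.ActivityScript("V1", (seg,))


def jump_script(seed: int) -> sd.ActivityScript:
    """Quiet/walk/jump/walk script used by the synchronization suite."""
    rng = np.random.default_rng(seed)
    t_jump = 6.0 + rng.uniform(-0.5, 0.5)
    segs = (
        sd.Segment("3a", 1.0, 1.5, direction_deg=0.0, speed=8.0),
        sd.Segment("jump", float(t_jump), 1.5, direction_deg=90.0, speed=18.0,
                   profile="bump"),
        sd.Segment("3b", 10.0, 1.5, direction_deg=180.0, speed=8.0),
    )
    return sd.ActivityScript("V1", segs, tail=3.0)
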