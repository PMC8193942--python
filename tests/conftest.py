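import numpy as np
import pytest

from gazeits import GeneratorConfig, generate_dataset
from gazeits.gaze_io import GazeRecording, Trial


@pytest.fixture(scope="session")
def small_dataset():
    """40 trials, 250 Hz / 10 s, defaults — shared across event tests."""
    cfg = GeneratorConfig(sampling_rate_hz=250, trial_length_s=10,
                          n_participants=5, trials_per_participant=8, seed=7)
    return generate_dataset(cfg)


def make_trial(x, y, fs=250.0, valid=None, vergence=1.0, pupil=3.5,
               trial_id="t0", participant="p0", task="task0", condition="A"):
    """Trial with hand-specified average-gaze path, split binocularly."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    ts = np.arange(n) / fs
    rec = GazeRecording(
        sampling_rate=fs, timestamps=ts,
        left_x=x + vergence / 2, left_y=y.copy(),
        right_x=x - vergence / 2, right_y=y.copy(),
        left_pupil=np.full(n, pupil), right_pupil=np.full(n, pupil),
        valid=np.asarray(valid, dtype=bool),
    )
    return Trial(recording=rec, trial_id=trial_id, participant_id=participant,
                 task_id=task, condition=condition)


@pytest.fixture
def constant_gaze_trial():
    n = 500  # 2 s at 250 Hz
    return make_trial(np.full(n, 3.0), np.full(n, -1.0))
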