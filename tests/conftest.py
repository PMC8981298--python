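import numpy as np
import pytest

from freegait.cohort import GaitProfile


@pytest.fixture
def hc_profile() -> GaitProfile:
    return GaitProfile(group="HC", mean_step_time=0.53, mean_step_length=0.66,
                       step_time_sd=0.02, step_length_sd=0.02,
                       asym_step_time=0.01, asym_step_length=0.01,
                       swing_fraction=0.76, sensor_height=1.05)


@pytest.fixture
def quiet_profile() -> GaitProfile:
    """Deterministic gait: no step-to-step noise, no asymmetry."""
    return GaitProfile(group="HC", mean_step_time=0.55, mean_step_length=0.60,
                       step_time_sd=0.0, step_length_sd=0.0,
                       asym_step_time=0.0, asym_step_length=0.0,
                       swing_fraction=0.76, sensor_height=1.0)


def match_events(true_times: np.ndarray, det_times: np.ndarray,
                 tol: float = 0.05) -> tuple[float, float, np.ndarray]:
    """(matched fraction, false-positive fraction, per-match errors)."""
    true_times = np.asarray(true_times, float)
    det_times = np.asarray(det_times, float)
    if len(det_times) == 0:
        return 0.0, 0.0, np.array([])
    errs = []
    used = np.zeros(len(det_times), bool)
    for t in true_times:
        j = int(np.argmin(np.abs(det_times - t)))
        d = abs(det_times[j] - t)
        if d <= tol:
            errs.append(d)
            used[j] = True
    matched = len(errs) / max(len(true_times), 1)
    fp = float(np.mean(~used)) if len(det_times) else 0.0
    return matched, fp, np.array(errs)
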