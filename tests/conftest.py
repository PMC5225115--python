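import numpy as np
import pytest

from warmpet.io_pet import FrameSchedule, TimeActivityCurve, default_schedule


@pytest.fixture(scope="session")
def schedule() -> FrameSchedule:
    return default_schedule()


def make_exponential_tac(schedule: FrameSchedule, peak_value: float, k: float,
                         peak_mid_time: float = 2.5) -> TimeActivityCurve:
    """Analytic washout curve: linear rise to the peak frame, then exact
    mono-exponential decay in frame mid-time. The log-signal is exactly
    linear after the peak, so trapezoidal integration of the washout
    log-integral is exact and closed forms apply."""
    mid = schedule.mid_times
    activity = np.empty_like(mid)
    rising = mid < peak_mid_time
    # strictly below peak before it, so the peak frame is the unique maximum
    activity[rising] = peak_value * 0.5 * (1.0 + mid[rising] / peak_mid_time) * 0.9
    activity[~rising] = peak_value * np.exp(-k * (mid[~rising] - peak_mid_time))
    return TimeActivityCurve(schedule, activity)


@pytest.fixture(scope="session")
def exp_tac_factory(schedule):
    def factory(peak_value: float, k: float, peak_mid_time: float = 2.5):
        return make_exponential_tac(schedule, peak_value, k, peak_mid_time)

    return factory
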