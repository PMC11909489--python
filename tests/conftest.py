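import numpy as np
import pytest

from gamekin.data_model import DeviceProfile, TouchTrace
from gamekin import tasks


@pytest.fixture
def device() -> DeviceProfile:
    return DeviceProfile()


@pytest.fixture
def market_task():
    return tasks.default_market_task()


@pytest.fixture
def race_task():
    return tasks.default_race_task()


@pytest.fixture
def message_spec():
    return tasks.default_message_task()


def make_trace(t, x, y, pointer_id=0, events=None) -> TouchTrace:
    t = np.asarray(t, float)
    if events is None:
        events = ["move"] * len(t)
        events[0], events[-1] = "down", "up"
    return TouchTrace(t=t, x=np.asarray(x, float), y=np.asarray(y, float),
                      events=events, pointer_id=pointer_id)


@pytest.fixture
def trace_factory():
    return make_trace
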