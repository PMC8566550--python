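import numpy as np
import pytest

from synphys.traces import TimeSeriesTrace, WindowSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20241005)


@pytest.fixture
def flat_dff_trace():
    """30 s noise-free dF/F trace at 100 ms sampling, all zeros."""
    t = np.arange(0.0, 30.0, 0.1)
    return TimeSeriesTrace(trace_id="flat", t=t, dff=np.zeros_like(t))


@pytest.fixture
def baseline_window():
    return WindowSpec(0.0, 10.0)


@pytest.fixture
def response_window():
    return WindowSpec(10.0, 20.0)


def make_dff_trace(dff, dt=0.1, trace_id="tr", genotype=""):
    dff = np.asarray(dff, dtype=float)
    t = np.arange(dff.size) * dt
    return TimeSeriesTrace(trace_id=trace_id, t=t, dff=dff, genotype=genotype)
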