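import numpy as np
import pytest

from nirscouple.timeseries import Recording, TimeSeries


def make_recording(duration: float = 660.0, seed: int = 0,
                   nirs_rate: float = 20.0, abp_rate: float = 1000.0) -> Recording:
    """Small hand-built five-channel recording (not via the generator)."""
    rng = np.random.default_rng(seed)
    tn = np.arange(int(duration * nirs_rate)) / nirs_rate
    ta = np.arange(int(duration * abp_rate)) / abp_rate
    channels = {}
    for side in ("L", "R"):
        o2 = 30 + np.cos(2 * np.pi * 0.04 * tn) + 0.8 * np.cos(2 * np.pi * 0.1 * tn)
        o2 = o2 + rng.normal(0, 0.05, tn.size)
        hh = 18 + rng.normal(0, 0.05, tn.size)
        channels[f"O2Hb_{side}"] = TimeSeries(o2, nirs_rate, f"O2Hb_{side}", "umol/L")
        channels[f"HHb_{side}"] = TimeSeries(hh, nirs_rate, f"HHb_{side}", "umol/L")
    abp = 90 + 20 * np.cos(2 * np.pi * 1.1 * ta) + rng.normal(0, 0.5, ta.size)
    channels["ABP"] = TimeSeries(abp, abp_rate, "ABP", "mmHg")
    return Recording(channels, subject_id="T000")


@pytest.fixture(scope="session")
def small_recording() -> Recording:
    return make_recording()
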