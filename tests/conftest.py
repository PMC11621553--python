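import numpy as np
import pytest

from caspike import FluorescenceTrace
from caspike.simulate import simulate_stack


@pytest.fixture
def worked_trace() -> FluorescenceTrace:
    """11 samples of 100 with one excursion to 140 at sample 5, dt = 5 s."""
    values = [100.0] * 11
    values[5] = 140.0
    return FluorescenceTrace(nucleus_id="hand", values=values, dt=5.0)


@pytest.fixture
def square_mask() -> np.ndarray:
    m = np.zeros((8, 8), dtype=bool)
    m[2:4, 2:4] = True
    return m


@pytest.fixture
def bimodal_stack(square_mask):
    """4 slices, background 10, a 2x2 square at (60, 80, 100, 120), no noise."""
    return simulate_stack(
        (4, 8, 8), background=10, foreground_regions=[(square_mask, [60, 80, 100, 120])],
        noise_sigma=0.0, seed=0,
    )


def naive_snr(values, dt=5.0, mode="relative"):
    """Direct-loop oracle for the SNR definition (independent of the package)."""
    k10 = round(10.0 / dt)
    k15 = round(15.0 / dt)
    out = []
    n = len(values)
    for t in range(k15, n - k15):
        b = (values[t - k15] + values[t - k10] + values[t + k10] + values[t + k15]) / 4.0
        out.append((values[t] - b) / b if mode == "relative" else values[t] - b)
    return out, k15


def naive_peaks(snr_values, offset, theta=0.3):
    """Direct-loop oracle for run extraction: (run_start, run_end, apex, apex_snr)."""
    peaks = []
    i = 0
    n = len(snr_values)
    while i < n:
        if snr_values[i] >= theta:
            j = i
            while j + 1 < n and snr_values[j + 1] >= theta:
                j += 1
            apex = i
            for k in range(i, j + 1):
                if snr_values[k] > snr_values[apex]:
                    apex = k
            peaks.append((i + offset, j + offset, apex + offset, snr_values[apex]))
            i = j + 1
        else:
            i += 1
    return peaks
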