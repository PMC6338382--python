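import numpy as np
import pytest

from wolkdr.monitoring import DamRecord, TransmissionScreen


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def backcross_screen() -> TransmissionScreen:
    """The published maternal-transmission screen reconstructed from its counts.

    249 dams, one uninfected; 1932 screened larvae, 1898 infected. The
    uninfected dam contributed 23 larvae, all uninfected; the remaining 11
    uninfected larvae are spread one per dam across infected dams (any
    arrangement with a per-dam max below 23 yields the same totals).
    """
    dams = [DamRecord("U0000", False, 0, 23)]
    # 248 infected dams sharing 1909 larvae: 173 dams of 8, 75 dams of 7
    sizes = [8] * 173 + [7] * 75
    assert sum(sizes) == 1909
    uninfected_left = 11
    for i, size in enumerate(sizes):
        u = 1 if uninfected_left > 0 else 0
        uninfected_left -= u
        dams.append(DamRecord(f"D{i:04d}", True, size - u, u))
    screen = TransmissionScreen(tuple(dams))
    assert sum(d.larvae_total for d in screen.dams) == 1932
    assert sum(d.larvae_infected for d in screen.dams) == 1898
    return screen
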