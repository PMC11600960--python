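import numpy as np
import pytest

from blasteeg.recording import MultichannelRecording, default_electrode_coords


@pytest.fixture
def make_recording():
    """Factory: wrap a data array (or generate white noise) as a recording."""

    def _make(data=None, sfreq=500.0, n_channels=4, duration=10.0, seed=0):
        if data is None:
            rng = np.random.default_rng(seed)
            data = rng.standard_normal((int(duration * sfreq), n_channels))
        n_channels = data.shape[1]
        return MultichannelRecording(
            data=data,
            sfreq=sfreq,
            ch_names=[f"ch{i:02d}" for i in range(n_channels)],
            coords=default_electrode_coords(n_channels),
        )

    return _make
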