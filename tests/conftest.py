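import numpy as np
import pytest

from mechpatch.synthetic_data import (
    GatingParams,
    TraceNoise,
    build_ramp_protocol,
    simulate_patch_trace,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def ramp_protocol():
    return build_ramp_protocol()


@pytest.fixture(scope="session")
def make_ramp_trace(ramp_protocol):
    """Factory for synthetic ramp traces with known ground truth."""

    def _make(
        n_channels=1,
        p50=-25.0,
        slope_k=-4.0,
        single_channel_current=0.98,
        leak_slope=0.04,
        leak_offset=0.5,
        noise_sd=0.2,
        seed=0,
        total_rate=1000.0,
    ):
        gating = GatingParams(
            p50=p50,
            slope_k=slope_k,
            total_rate=total_rate,
            n_channels=n_channels,
            single_channel_current=single_channel_current,
        )
        noise = TraceNoise(
            leak_slope=leak_slope,
            leak_offset=leak_offset,
            noise_sd=noise_sd,
            seed=seed,
        )
        return simulate_patch_trace(ramp_protocol, gating, noise)

    return _make
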