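"""Shared fixtures: compact recording protocols and constructed traces."""

import numpy as np
import pytest

from mitopore.simulate import RecordingProtocol, synthesize_trace


@pytest.fixture
def protocol_10s() -> RecordingProtocol:
    return RecordingProtocol(duration=10.0)


def square_trace(segments, duration=None, noise_sd=0.0, seed=0,
                 filtered=False, ramps=None, protocol=None):
    """Constructed piecewise-constant trace with known level path."""
    if protocol is None:
        total = sum(d for d, _ in segments)
        protocol = RecordingProtocol(duration=total)
    return synthesize_trace(segments, protocol, ramps=ramps,
                            noise_sd=noise_sd, seed=seed, filtered=filtered)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
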