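import numpy as np
import pytest

from hypnodyn.types import Hypnogram, State


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def hand_hypnogram():
    """W,W,N,W,N,N,N,R,R,W — the hand-countable 10-epoch sequence."""
    return Hypnogram(labels=tuple("W W N W N N N R R W".split()), epoch_s=5.0)


@pytest.fixture
def alternating_hypnogram():
    """Strictly alternating NREM/W: completely fragmented for both states."""
    return Hypnogram(labels=tuple(["N", "W"] * 50), epoch_s=5.0)


def make_session(labels, fs=512.0, epoch_s=5.0, seed=0, **eeg_kwargs):
    """Small synthetic session helper for signal-level tests."""
    from hypnodyn import synthetic as syn

    h = Hypnogram(labels=tuple(labels), epoch_s=epoch_s)
    params = syn.default_eeg_params(fs=fs)
    if eeg_kwargs:
        from dataclasses import replace

        params = replace(params, **eeg_kwargs)
    return h, syn.synthesize_eeg(h, params, seed=seed)
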