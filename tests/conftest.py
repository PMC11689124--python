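import pytest

import cardiotfa as ct


@pytest.fixture(scope="session")
def clean_bp_60bpm():
    """60 s of unforced 60 beats/min BP with no R-R jitter influence on levels."""
    return ct.simulate_bp_waveform(
        hr=60, sbp=120, dbp=80, forcing_freq=0.0, forcing_amp=0.0,
        duration=60, sample_rate=100, seed=7,
    )


@pytest.fixture(scope="session")
def forced_recording():
    """240 s of 90 beats/min BP forced at 0.05 Hz with 10 mmHg amplitude."""
    return ct.simulate_bp_waveform(
        hr=90, forcing_freq=0.05, forcing_amp=10.0, duration=240,
        sample_rate=100, seed=21,
    )


@pytest.fixture(scope="session")
def transferred_recording(forced_recording):
    """The forced recording with noiseless eucapnic velocity channels."""
    truths = ct.default_transfer_truths("eucapnia", 0.05)
    rec, truth = ct.apply_transfer(
        forced_recording, truths, forcing_freq=0.05, noise_sd=0.0, seed=22
    )
    return rec, truth


#: Shared alias so tests exercise the package's own calibration simulator.
make_metric_table = ct.stats.simulate_metric_table
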