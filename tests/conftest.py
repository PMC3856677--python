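import numpy as np
import pytest

import respalign as ra


@pytest.fixture(scope="session")
def md10():
    return ra.MaximalDisplacement(subject_id="S", md=10.0)


@pytest.fixture(scope="session")
def reader_trial():
    """One male-reader normal-condition trial (recording, labels, truth)."""
    return ra.simulate_reader_trial(ra.MALE_READER, "T01", "N", seed=7)


@pytest.fixture(scope="session")
def listener_trial(reader_trial):
    _, _, truth = reader_trial
    return ra.simulate_listener_trial(
        ra.DEFAULT_LISTENER, truth, "N", seed=7, listener_id="S01", trial_id="t01"
    )


def segment(rec, md=None):
    """Standard preprocessing + detection chain used across tests."""
    filt = ra.filter_resample(rec)
    trace = ra.combine_bands(filt)
    events = ra.detect_inhalations(trace)
    if md is None:
        return trace, events, None
    cycles = ra.build_cycles(events, trace, md, subject_id=rec.subject_id,
                             trial_id=rec.trial_id)
    return trace, events, cycles


@pytest.fixture(scope="session")
def segmented_listener(listener_trial, md10):
    rec, truth = listener_trial
    trace, events, cycles = segment(rec, md10)
    return dict(rec=rec, truth=truth, trace=trace, events=events, cycles=cycles)
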