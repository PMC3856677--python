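"""Test listener-reader breathing alignment with a surrogate null.

Simulates listeners phase-locked to 15% of the reader's breathing cycle,
computes posI (the fractional position of each listener inhalation onset
inside the containing reader cycle), re-pairs listeners with readers of
other texts in the same condition (a derangement) to build the chance
distribution, and compares the two with a Kolmogorov-Smirnov test.
"""

from dataclasses import replace

import numpy as np

import respalign as ra
from respalign.alignment import posI_observations

listener = replace(ra.DEFAULT_LISTENER, coupling_mode="phase_locked",
                   coupling_phase=0.15, coupling_jitter_sd=0.03, fs=50.0)
reader = replace(ra.FEMALE_READER, trial_dur=120.0, fs=50.0)

design = ra.make_design(4, readers=("F",), n_texts_per_condition=5, seed=3)
reader_onsets, listener_onsets = {}, {}
for r, text, cond in (design[["reader", "text", "condition"]]
                      .drop_duplicates().itertuples(index=False)):
    _, labels, truth = ra.simulate_reader_trial(reader, text, cond, seed=3,
                                                reader_id=r)
    reader_onsets[(r, text, cond)] = np.asarray(truth.onsets) - labels.speech_onset_s
for row in design.itertuples(index=False):
    _, labels, truth = ra.simulate_reader_trial(reader, row.text, row.condition,
                                                seed=3, reader_id=row.reader)
    _, lt = ra.simulate_listener_trial(listener, truth, row.condition, seed=3,
                                       listener_id=row.listener,
                                       trial_id=str(row.trial_index))
    listener_onsets[(row.listener, int(row.trial_index))] = (
        np.asarray(lt.onsets) - labels.speech_onset_s
    )

original = posI_observations(design, listener_onsets, reader_onsets)
surrogate = ra.random_association(design, listener_onsets, reader_onsets, seed=3)

print(f"original posI observations: {len(original)}")
print(f"density mode of original posI: {ra.posI_mode(original['posI']):.3f} "
      "(locking phase was 0.15)")
ks = ra.ks_two_sample(original["posI"], surrogate["posI"])
print(f"KS(original, surrogate): D = {ks.D:.3f}, p = {ks.p:.2e}")
# A significant KS against the surrogate (random-pairing) null is the
# evidence for genuine temporal alignment; independent listeners give
# D near 0 and large p here.
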