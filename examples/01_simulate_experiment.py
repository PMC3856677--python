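"""Simulate a small playback experiment and write it as a CSV bundle.

Builds a counter-balanced design (listeners split across the two readers,
normal/loud order alternating), generates reader and listener two-band
breathing traces with full ground truth, and writes everything to disk.
"""

from dataclasses import replace

import respalign as ra
from respalign.io import write_bundle

design = ra.make_design(n_listeners=4, n_texts_per_condition=3, seed=1)
print(design.head(6).to_string(index=False))

fast = {
    "F": replace(ra.FEMALE_READER, trial_dur=30.0),
    "M": replace(ra.MALE_READER, trial_dur=30.0),
}
bundle = ra.simulate_experiment(design, reader_params=fast, seed=1)
out = write_bundle(bundle, "scratch_bundle")

print(f"\nlistener trials: {bundle.n_listener_trials}")
print(f"reader recordings: {len(bundle.reader_trials)} (one per reader/text/condition)")
print(f"bundle written to {out}/ (traces/, labels/, vc/, truth/, design.csv)")
# Each listener trial row of design.csv points at one reader recording;
# ground-truth cycle tables make every downstream stage checkable.
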