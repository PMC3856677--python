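# Methods

`respalign` analyzes breathing kinematics recorded with two
inductance-plethysmography bands (rib cage and abdomen) while
participants listen to pre-recorded read speech.  This note documents the
models and procedures, the parameters that matter, what the synthetic
generator emulates (and does not), and the numerical choices made where
the design was genuinely open.

## Signal model and preprocessing

Each trial is a two-channel displacement trace sampled uniformly.  The
rib-cage and abdominal channels are summed (weights configurable; 1:1 by
default, with the 2:1 rib-cage weighting used in lung-volume estimation
available as a variant) and the sum proxies lung-volume change.  Because
the bands are not calibrated to liters, amplitudes are normalized per
subject: the maximal displacement (MD) is the largest trough-to-peak
excursion across the subject's vital-capacity maneuvers, and all
amplitudes are reported in %MD.  MD maneuvers are delimited by label
intervals when present, otherwise detected automatically as monotone
trough-to-peak sweeps exceeding 50% of the trace's global range.

Filtering is zero-phase FIR (Hamming window, forward–backward
application): cycle *timing* is the quantity of scientific interest and
any group delay would bias every onset.  The default band is
0.05–5 Hz — the high-pass removes baseline drift, the low-pass removes
sensor noise, and the passband spans the breathing fundamental
(~0.2–0.5 Hz) and the harmonics that shape the fast inhalation limb.  A
1–40 Hz band, matching a setting sometimes quoted for this hardware
chain, is available via `--literal-band`, but it suppresses the breathing
fundamental and is not recommended.  Filter order adapts to the band
edge and is capped by the trace length so forward–backward padding is
always possible.  Resampling (default target 200 Hz, ample for onset
detection) is polyphase; output length is `round(n·target_fs/fs)`.

## Cycle segmentation

Inhalation is the fast limb of the breathing movement, so each cycle is
anchored on a positive velocity peak.  Velocity is the central-difference
derivative of a 2 Hz zero-phase low-passed copy of the trace; human
inhalations last several hundred milliseconds or more, so their velocity
content lies below ~2.5 Hz and the smoothing is physiologically lossless
while removing noise-derivative wiggles.

Detection contract (kept deliberately scan-reproducible):

- candidate peaks: positive local velocity maxima (first sample of a
  plateau) with topographic prominence at least `min_prominence`;
- the default prominence floor is the larger of 5% of the displacement
  range per second and 20% of the 95th percentile of positive velocity.
  The first term alone admits noise-velocity peaks at realistic SNR; the
  percentile term scales with genuine inhalation peaks yet is insensitive
  to rare artifact spikes (which occupy few samples);
- refractory rule: peaks closer than `min_cycle_s` (default 1 s) to a
  taller accepted peak are suppressed, tallest first;
- onset: last sample at or below `onset_frac` (default 10%) of the peak
  velocity before the peak; offset: first sample at or below
  `offset_frac` of the peak after it.  The symmetric 10% falling-limb
  offset is the default because a 90% falling-limb crossing would end
  inhalation near its fastest point; the 90% convention remains
  available (`offset_frac=0.9`, `--literal-offset`).

Consecutive onsets define cycles: durC (onset to next onset), the
inhalation phase I (onset to inhalation offset, duration durI, amplitude
ampI in %MD) and the post-inhalation phase PI (everything else —
exhalation plus plateaus; exhalation offsets are not labeled because the
exhalation velocity peak is unreliable during speech-like breathing).
durI + durPI = durC exactly.  The last detected onset closes the final
cycle but starts none.

Non-breathing movements are flagged, not silently removed: any cycle
overlapping an interval where |velocity| exceeds `vel_thresh_mult`
(default 5) times the median per-cycle inhalation peak velocity, or
overlapping a user-supplied edit-list interval (the replacement for
interactive boundary correction), carries an `artifact` flag.  Per
listener, cycles with ampI or durC outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR]
(quartiles by linear interpolation, disjunctive rule, computed over that
listener's retained cycles pooled across conditions) carry an `outlier`
flag; per-listener and mean exclusion fractions are reported.  Flagged
cycles stay in the table and are excluded from analysis.

For reader recordings, each cycle's syllable rate rSyll is the summed
syllable count of the speech chunks starting inside the cycle divided by
their summed duration; cycles without speech yield no value.

## Phase alignment (posI) and the surrogate null

Listener and reader clocks are aligned at speech onset (each side
shifted by its own label).  Each listener inhalation onset is placed
inside the reader cycle containing it (half-open convention,
onset_i ≤ t < onset_{i+1}), giving posI = (t − onset_i)/durC_i ∈ [0, 1);
onsets outside the reader's cycle span are dropped rather than clamped —
containment is the only reading consistent with a 0–100% phase.  The
first listener cycle of each trial is flagged so task-onset
synchronization can be reported separately.

Because two quasi-periodic signals align occasionally by chance, the
original pairing is compared against surrogate pairings: per listener and
condition, texts are deranged (uniform random derangement by rejection,
so no trial keeps its own reader recording) and posI is recomputed
against the surrogate reader trial.  Listener cycles are never modified.
One draw is the default (`n_draws` pools more, each seeded).
Distributions are compared with the two-sample Kolmogorov–Smirnov test
(scipy; exact p for small samples).  Pooling cycles across listeners
ignores within-listener dependence; the resulting p-values are
descriptive of the pooled distribution, a caveat inherited from the
analysis design.  Density curves use a Gaussian KDE with Silverman
bandwidth computed on the original sample and reflected at 0 and 1
(posI is a phase), for display and the mode diagnostic only.

## Mixed-effects analysis

The condition analysis fits durC and ampI (per retained cycle) with
Condition, Order and Reader as treatment-coded fixed factors (all
interactions by default; references: normal condition, female reader)
and crossed random intercepts for Listener and Text.  statsmodels'
MixedLM lacks a native crossed-groups interface, so the crossed
intercepts are expressed as variance components on a single
all-encompassing group — algebraically the same model.

P-values for fixed terms default to a seeded parametric bootstrap
(default 1000 resamples): responses are simulated from the fitted null
(intercept + random effects + residual, all fixed effects removed), the
full model is refit per replicate, and each term's observed |t| is
ranked in its null distribution, p = (1 + #{|t*| ≥ |t|})/(1 + B).  This
global-null scheme is exact for the calibration setting and standard for
resampling tests of factorial terms.  Asymptotic Wald p-values
(`p_method="wald"`) are the fast mode used in large repeated-simulation
studies.  When the quantile–quantile correlation of the residuals with
normal quantiles falls below 0.98 the response is log-transformed (the
response must then be strictly positive); the automatic criterion
replaces a visual diagnostic with a testable one.

Trial-progression contrasts (1 vs 5: adaptation over the first
condition; 5 vs 6: reset at the condition change; 6 vs 10: adaptation
over the second condition) are computed within Reader × Order splits:
Trial (levels 1, 5, 6, 10) fixed, Listener a random intercept, each pair
tested as a difference of coefficients.  Cycles are first averaged to
one value per listener and trial: cycles within a trial share the text
and the listener's momentary state, so cycle-level fits would overstate
the effective sample size.  `split_by=()` pools all listeners into one
fit, the higher-powered variant used when a single detection statement
is needed.

## The synthetic generator

No recordings of this paradigm are public, so the generator is the
package's test bed and defines the study conditions.

Reader trials: a renewal sequence of cycles (Gaussian durations
truncated at half the mean), each rendered as a raised-cosine rise over
`inhal_frac`·durC followed by an exponential decay to baseline with time
constant durPI/4 (back to ~2% of the peak before the next onset; one
unambiguous velocity peak per phase).  Each exhalation carries one
labeled speech chunk whose syllable count follows the condition-shifted
per-cycle mean and whose duration follows the syllable rate.  Presets
encode the study's two readers: the male reader breathes slower
(5.5 s cycles vs 3.0 s), deeper, with more syllables per cycle; loud
speech adds +1.1 s and deeper inhalation for him, little duration change
but fewer syllables per cycle for her; slow speech deepens her
inhalation and cuts syllables per cycle.

Listener trials: quiet-ish breathing at 3.3 s mean cycle duration and
~15 %MD inhalation (the listening-condition averages; quiet-breathing
baselines were never analyzed in the source study, so listening means
are the defensible default).  Condition shifts follow the listening
results (loud: −139 ms, slightly shallower; slow: +178 ms).  Three
coupling modes: `independent` (truncated-Gaussian renewal),
`poisson` (homogeneous Poisson onsets — the analytic null under which
posI is Uniform(0,1)), and `phase_locked` (one onset per reader cycle at
`coupling_phase` + Gaussian jitter, both cycle fractions).  Movement
artifacts are 150–300 ms triangular spikes with peak velocity 6–10×
the typical inhalation peak, at `artifact_rate` events/minute, recorded
in the ground truth.  The final ground-truth onset is rendered as a real
inhalation (with room to complete before trial end) so every truth onset
exists in the trace.

Both channels are gain-split copies of one waveform (gains sum to 1,
drawn per trial) plus independent Gaussian noise at the configured SNR
(default 20 dB for listeners) — the synchronized-bands assumption.  VC
maneuvers are cosine trough-to-peak sweeps with a few percent
trial-to-trial variation; the largest equals the subject's nominal
amplitude exactly, so MD recovery is checkable.  All randomness flows
through generators keyed by (master seed, role, subject, trial), making
every trial independently reproducible and whole bundles bit-identical
across reruns.

What the generator does not emulate — and hence what passing tests do
not show about real data: band asynchrony and paradoxical breathing,
amplitude drift and posture change, sighs and swallows with breathing-like
velocity profiles, serial correlation of cycle durations, non-Gaussian
duration distributions, or speech-planning structure in chunking.  Tests
passing here certify the machinery, not the biology.

For mixed-model calibration studies (type-I error, power, contrast
detection), cycle-parameter tables are drawn directly from the model's
own data-generating process (mean + condition shift + listener and text
intercepts + noise; `simulate_parameter_table`) rather than through
trace synthesis — the quantity under test is the estimator, and
trace-level recovery is validated separately.  Default sizes follow the
study: 26 listeners × 10 trials (condition studies), 12 listeners
(progression studies), ~15 retained cycles per trial.

## Numerical choices and degenerate inputs

- Sample k lives at t0 + k/fs, 0-based; all times in seconds.
- Detection works at sample resolution (no sub-sample interpolation):
  exact oracle equivalence is worth more than <5 ms of precision at
  200 Hz.
- Ties: a velocity plateau's first sample is the peak; equal-height
  peaks are accepted nearest-first in the refractory rule.
- Quartiles use linear interpolation (matching the sort-based oracle);
  an IQR of zero flags nothing.
- Listeners with fewer than 4 retained cycles skip outlier filtering
  with a warning; empty strata are omitted from posI reports; a KS test
  needs two values per side.
- Traces shorter than 3 samples, flat VC traces, non-positive MD, and
  single-level fixed factors raise typed errors
  (`DegenerateInputError`, `ParameterError`, `DesignError`).
- Mixed models fit by REML, L-BFGS first with BFGS and Powell fallbacks
  on numerical failure.

## Known limitations

- posI inference pools cycles and ignores within-listener dependence.
- The bootstrap p-values are calibrated under the global null of the
  tested fixed effects; per-term p-values in the presence of large other
  effects are approximate.
- Artifact flagging is velocity-threshold-based; slow artifacts
  (posture drift) pass it and are caught, if at all, by the IQR rule.
- The per-subject %MD scale depends on VC maneuver effort, as it does
  for the real measurement.
- Sign conventions of mixed-model t-values depend on factor coding;
  comparisons across software require matching the treatment coding
  stated above.
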