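"""Inhalation detection, cycle construction, artifact and outlier flags."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import respalign as ra
from oracles import iqr_flags, scan_detect
from respalign.cycles import artifact_windows_from_velocity, cycles_to_table, velocity
from respalign.types import CombinedTrace, ContractError, DegenerateInputError


def _trace(values, fs=200.0):
    return CombinedTrace(fs=fs, values=np.asarray(values, dtype=float))


class TestVelocity:
    def test_linear_ramp(self):
        t = np.arange(1000) / 200.0
        v = velocity(_trace(2.0 * t), smooth_hz=0)
        assert np.allclose(v[10:-10], 2.0, atol=1e-9)

    def test_constant(self):
        v = velocity(_trace(np.full(500, 1.3)), smooth_hz=0)
        assert np.allclose(v, 0.0, atol=1e-12)

    def test_sinusoid_peak(self):
        fs, f, A = 200.0, 0.4, 2.0
        t = np.arange(int(30 * fs)) / fs
        v = velocity(_trace(A * np.sin(2 * np.pi * f * t)))
        assert np.max(v) == pytest.approx(2 * np.pi * f * A, rel=0.02)

    def test_too_short_rejected(self):
        with pytest.raises(DegenerateInputError):
            velocity(_trace([1.0, 2.0]))


class TestDetect:
    def test_matches_brute_force_scan_on_random_traces(self):
        """The vectorized detector equals the exhaustive sample scan."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(300, 4000))
            fs = float(rng.choice([50.0, 100.0, 200.0]))
            # random smooth-ish trace: a few sinusoids plus noise
            t = np.arange(n) / fs
            x = sum(
                rng.uniform(0.2, 1.5) * np.sin(2 * np.pi * rng.uniform(0.1, 0.8) * t
                                               + rng.uniform(0, 2 * np.pi))
                for _ in range(3)
            ) + 0.05 * rng.normal(size=n)
            trace = _trace(x, fs)
            prom = float(rng.uniform(0.05, 1.0))
            min_cyc = float(rng.uniform(0.3, 1.5))
            events = ra.detect_inhalations(
                trace, min_prominence=prom, min_cycle_s=min_cyc, smooth_hz=2.0
            )
            v = velocity(trace, smooth_hz=2.0)
            expected = scan_detect(v, fs, 0.0, 0.1, 0.1, min_cyc, prom)
            got = [(e.onset_t, e.offset_t, e.peak_vel_t, e.peak_vel) for e in events]
            assert got == expected

    def test_recovers_true_onsets(self, segmented_listener):
        truth = segmented_listener["truth"]
        det = np.array([e.onset_t for e in segmented_listener["events"]])
        for t in truth.onsets:
            assert np.min(np.abs(det - t)) <= 0.05

    def test_refractory_suppresses_close_peaks(self):
        fs = 200.0
        t = np.arange(int(4 * fs)) / fs
        # two rises 0.2 s apart inside a 1 s refractory window
        x = np.zeros_like(t)
        for start in (1.0, 1.2):
            m = (t >= start) & (t < start + 0.15)
            x[m] += 0.5 * (1 - np.cos(np.pi * (t[m] - start) / 0.15))
        events = ra.detect_inhalations(_trace(x, fs), min_cycle_s=1.0,
                                       min_prominence=0.5, smooth_hz=0)
        assert len(events) == 1

    def test_monotone_decreasing_yields_nothing(self):
        x = np.linspace(5.0, 0.0, 2000)
        assert ra.detect_inhalations(_trace(x), min_prominence=0.1) == []


class TestBuildCycles:
    def _events(self, times):
        return [
            ra.InhalationEvent(onset_t=t, offset_t=t + 0.8, peak_vel_t=t + 0.4,
                               peak_vel=1.0)
            for t in times
        ]

    def test_durations_from_onsets(self, md10):
        trace = _trace(np.zeros(2000))
        cycles = ra.build_cycles(self._events([0.0, 3.0, 6.0]), trace, md10)
        assert [c.durC for c in cycles] == [3.0, 3.0]
        assert len(cycles) == 2

    def test_amp_in_percent_md(self):
        fs = 200.0
        x = np.zeros(2000)
        x[int(0.8 * fs) :] = 0.3  # rise of 0.3 units completed at offset
        md = ra.MaximalDisplacement("S", 2.0)
        cycles = ra.build_cycles(self._events([0.0, 5.0]), _trace(x, fs), md)
        assert cycles[0].ampI == pytest.approx(15.0)

    def test_single_event_no_cycle(self, md10):
        assert ra.build_cycles(self._events([1.0]), _trace(np.zeros(1000)), md10) == []

    def test_unordered_events_rejected(self, md10):
        with pytest.raises(ContractError):
            ra.build_cycles(self._events([3.0, 1.0]), _trace(np.zeros(1000)), md10)

    def test_phase_partition_identity(self, segmented_listener):
        for c in segmented_listener["cycles"]:
            assert c.durI + c.durPI == pytest.approx(c.durC, abs=1e-12)


@pytest.fixture(scope="module")
def spiked(md10):
    """Clean listener trial with one injected movement spike in cycle 3."""
    from dataclasses import replace

    params = replace(ra.DEFAULT_LISTENER, snr_db=60.0)
    rec, truth = ra.simulate_listener_trial(params, None, "N", seed=31,
                                            duration=60.0)
    trace = ra.combine_bands(ra.filter_resample(rec))
    events = ra.detect_inhalations(trace)
    cycles = ra.build_cycles(events, trace, md10)
    c3 = cycles[3]
    mid = 0.5 * (c3.inhal_offset_t + c3.next_onset_t)
    values = trace.values.copy()
    t = trace.time
    width = 0.2
    vpk = max(e.peak_vel for e in events)
    height = 6.0 * vpk * width / 2.0
    m = (t >= mid) & (t <= mid + width)
    values[m] += height * (1 - np.abs((t[m] - mid - width / 2) / (width / 2)))
    return cycles, CombinedTrace(fs=trace.fs, values=values, t0=trace.t0)


class TestArtifacts:
    def test_spike_flags_exactly_its_cycle(self, spiked):
        cycles, trace = spiked
        flagged = ra.flag_artifacts(cycles, trace, vel_thresh_mult=4.0)
        hit = [c.cycle_index for c in flagged if "artifact" in c.flags]
        assert hit == [3]

    def test_clean_trace_no_flags(self, segmented_listener):
        flagged = ra.flag_artifacts(
            segmented_listener["cycles"], segmented_listener["trace"]
        )
        assert not any("artifact" in c.flags for c in flagged)

    def test_edit_list_covering_trial_flags_all(self, segmented_listener):
        flagged = ra.flag_artifacts(
            segmented_listener["cycles"], segmented_listener["trace"],
            edit_list=[(0.0, 1e6)],
        )
        assert all("artifact" in c.flags for c in flagged)

    def test_raising_threshold_never_adds_flags(self, spiked):
        cycles, trace = spiked
        counts = []
        for mult in (2.0, 4.0, 8.0, 16.0):
            flagged = ra.flag_artifacts(cycles, trace, vel_thresh_mult=mult)
            counts.append(sum("artifact" in c.flags for c in flagged))
        assert counts == sorted(counts, reverse=True)

    def test_window_detector_finds_injected_spike(self, spiked):
        cycles, trace = spiked
        wins = artifact_windows_from_velocity(cycles, trace, vel_thresh_mult=4.0)
        assert len(wins) >= 1


class TestOutlierFilter:
    def _table(self, dur, amp=None, listener="S01"):
        amp = amp if amp is not None else [15.0] * len(dur)
        return pd.DataFrame(
            dict(
                subject_id=listener,
                trial_id="t01",
                cycle_index=range(len(dur)),
                durC=dur,
                ampI_pctMD=amp,
                flags="",
            )
        )

    def test_gross_outlier_flagged(self):
        table, summary = ra.filter_outliers(self._table([1.0, 1.0, 1.0, 1.0, 100.0]))
        flagged = table["flags"].str.contains("outlier")
        assert list(flagged) == [False, False, False, False, True]
        assert summary.iloc[0]["excluded_frac"] == pytest.approx(0.2)

    def test_identical_values_none_flagged(self):
        table, _ = ra.filter_outliers(self._table([2.0] * 8))
        assert not table["flags"].str.contains("outlier").any()

    def test_disjunction_amp_or_dur(self):
        table, _ = ra.filter_outliers(
            self._table([3.0] * 7 + [3.0], [15.0] * 7 + [80.0])
        )
        assert table["flags"].str.contains("outlier").iloc[-1]

    def test_too_few_cycles_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            table, summary = ra.filter_outliers(self._table([1.0, 2.0, 3.0]))
        assert len(summary) == 0

    @given(
        hst.lists(hst.floats(0.5, 20.0), min_size=8, max_size=200),
        hst.lists(hst.floats(0.5, 60.0), min_size=8, max_size=200),
    )
    @settings(max_examples=40, deadline=None)
    def test_matches_sorted_quartile_oracle(self, dur, amp):
        n = min(len(dur), len(amp))
        dur, amp = dur[:n], amp[:n]
        table, _ = ra.filter_outliers(self._table(dur, amp))
        expected = iqr_flags(np.array(dur)) | iqr_flags(np.array(amp))
        got = table["flags"].str.contains("outlier").to_numpy()
        assert np.array_equal(got, expected)


class TestSyllableRate:
    def _cycle(self, onset, offset, nxt):
        return ra.BreathingCycle(onset_t=onset, inhal_offset_t=offset,
                                 next_onset_t=nxt, ampI=10.0, cycle_index=0)

    def test_single_chunk(self):
        labels = ra.IntervalLabels(
            "t", 0.0, 10.0, [ra.SpeechChunk(1.0, 3.5, syllables=10)]
        )
        out = ra.syllable_rate([self._cycle(0.0, 0.8, 5.0)], labels)
        assert out["rSyll"].iloc[0] == pytest.approx(4.0)

    def test_multiple_chunks_pooled(self):
        labels = ra.IntervalLabels(
            "t", 0.0, 10.0,
            [ra.SpeechChunk(1.0, 2.5, syllables=6), ra.SpeechChunk(3.0, 4.0, syllables=4)],
        )
        out = ra.syllable_rate([self._cycle(0.0, 0.8, 5.0)], labels)
        assert out["rSyll"].iloc[0] == pytest.approx(10.0 / 2.5)

    def test_cycle_without_chunk_absent(self):
        labels = ra.IntervalLabels("t", 0.0, 10.0, [ra.SpeechChunk(8.0, 9.0, 5)])
        out = ra.syllable_rate([self._cycle(0.0, 0.8, 5.0)], labels)
        assert len(out) == 0

    def test_generator_rates_recovered(self, reader_trial, md10):
        rec, labels, truth = reader_trial
        trace = ra.combine_bands(ra.filter_resample(rec))
        events = ra.detect_inhalations(trace)
        cycles = ra.build_cycles(events, trace, md10, trial_id="r1")
        out = ra.syllable_rate(cycles, labels)
        assert len(out) >= truth.n_cycles - 2
        assert out["rSyll"].mean() == pytest.approx(
            ra.MALE_READER.syllable_rate, rel=0.15
        )


def test_cycle_table_round_trip(segmented_listener):
    table = cycles_to_table(segmented_listener["cycles"])
    assert len(table) == len(segmented_listener["cycles"])
    assert np.allclose(table["durI"] + table["durPI"], table["durC"])
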