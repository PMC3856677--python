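"""Generator contracts: determinism, ground-truth geometry, coupling modes."""

import numpy as np
import pytest
from scipy import stats as sstats

import respalign as ra
from respalign.simulate import trial_rng
from respalign.types import ContractError, ParameterError


def test_same_seed_bit_identical():
    a = ra.simulate_reader_trial(ra.MALE_READER, "T01", "N", seed=3)
    b = ra.simulate_reader_trial(ra.MALE_READER, "T01", "N", seed=3)
    assert np.array_equal(a[0].ribcage, b[0].ribcage)
    assert np.array_equal(a[0].abdomen, b[0].abdomen)
    assert a[2].onsets == b[2].onsets and a[2].ampI == b[2].ampI
    c = ra.simulate_reader_trial(ra.MALE_READER, "T01", "N", seed=4)
    assert not np.array_equal(a[0].ribcage, c[0].ribcage)


def test_zero_variance_gives_constant_cycle_durations():
    from dataclasses import replace

    params = replace(ra.MALE_READER, cycle_dur_sd=0.0, condition_effects={})
    _, _, truth = ra.simulate_reader_trial(params, "T01", "N", seed=1)
    assert np.allclose(truth.durC, params.mean_cycle_dur)


def test_condition_effect_shifts_mean_cycle_duration():
    """A +1.1 s loud-speech offset must appear in the generated durations."""
    durs = {}
    for cond in ("N", "L"):
        d = []
        for k in range(12):
            _, _, truth = ra.simulate_reader_trial(
                ra.MALE_READER, f"T{k:02d}", cond, seed=11
            )
            d.extend(truth.durC)
        durs[cond] = np.mean(d)
    shift = durs["L"] - durs["N"]
    assert shift == pytest.approx(1.1, abs=0.35)


def test_bands_share_cycle_timing_exactly():
    """Onsets detected on the rib-cage channel alone match the abdomen
    channel alone to within one sample (noiseless): shared timing."""
    from dataclasses import replace

    params = replace(ra.DEFAULT_LISTENER, snr_db=90.0)
    rec, _ = ra.simulate_listener_trial(params, None, "N", seed=17, duration=60.0)
    ev = {}
    for name, series in (("rc", rec.ribcage), ("ab", rec.abdomen)):
        trace = ra.CombinedTrace(fs=rec.fs, values=series)
        ev[name] = [e.onset_t for e in ra.detect_inhalations(trace)]
    assert len(ev["rc"]) == len(ev["ab"])
    for a, b in zip(ev["rc"], ev["ab"]):
        assert abs(a - b) <= 1.0 / rec.fs + 1e-9


def test_ground_truth_counts_and_bounds(reader_trial):
    rec, _, truth = reader_trial
    assert truth.n_cycles == len(truth.onsets) - 1
    assert truth.onsets[-1] < rec.duration
    assert all(np.diff(truth.onsets) > 0)


def test_phase_locked_zero_jitter_is_point_mass(reader_trial):
    from dataclasses import replace

    _, _, rtruth = reader_trial
    params = replace(
        ra.DEFAULT_LISTENER, coupling_mode="phase_locked",
        coupling_phase=0.15, coupling_jitter_sd=0.0,
    )
    _, ltruth = ra.simulate_listener_trial(params, rtruth, "N", seed=5)
    r = np.asarray(rtruth.onsets)
    pos = ra.compute_posI(ltruth.onsets, r)["posI"]
    assert np.allclose(pos, 0.15, atol=1e-9)


def test_coupling_without_reader_truth_raises():
    from dataclasses import replace

    params = replace(ra.DEFAULT_LISTENER, coupling_mode="phase_locked")
    with pytest.raises(ContractError):
        ra.simulate_listener_trial(params, None, "N", seed=1)


def test_poisson_listener_posI_uniform():
    """Poisson arrivals land uniformly within reader cycles (analytic)."""
    from dataclasses import replace

    params = replace(ra.DEFAULT_LISTENER, coupling_mode="poisson", fs=50.0)
    rp = replace(ra.MALE_READER, trial_dur=400.0, fs=50.0, condition_effects={})
    pos = []
    k = 0
    while len(pos) < 2000:
        _, _, rtruth = ra.simulate_reader_trial(rp, f"T{k}", "N", seed=21)
        _, ltruth = ra.simulate_listener_trial(params, rtruth, "N", seed=21,
                                               trial_id=f"t{k}")
        pos.extend(ra.compute_posI(ltruth.onsets, np.asarray(rtruth.onsets))["posI"])
        k += 1
    p = sstats.kstest(np.asarray(pos), "uniform").pvalue
    assert p > 0.01


def test_artifact_rate_zero_and_positive():
    from dataclasses import replace

    none = replace(ra.DEFAULT_LISTENER, artifact_rate=0.0)
    _, truth = ra.simulate_listener_trial(none, None, "N", seed=2, duration=60.0)
    assert truth.artifact_windows == []
    some = replace(ra.DEFAULT_LISTENER, artifact_rate=6.0)
    _, truth = ra.simulate_listener_trial(some, None, "N", seed=2, duration=60.0)
    assert len(truth.artifact_windows) > 0
    for a, b in truth.artifact_windows:
        assert 0.1 <= b - a <= 0.3 + 1e-9


def test_vc_maneuver_scaling_and_determinism():
    vc = ra.simulate_vc(2.0, n_trials=3, seed=9)
    md = ra.compute_md(vc)
    assert md.md == pytest.approx(2.0, rel=0.02)
    vc1 = ra.simulate_vc(1.0, n_trials=1, seed=9)
    assert ra.compute_md(vc1).md == pytest.approx(1.0, rel=0.02)
    again = ra.simulate_vc(2.0, n_trials=3, seed=9)
    assert np.array_equal(vc.ribcage, again.ribcage)
    with pytest.raises(ParameterError):
        ra.simulate_vc(-1.0)


def test_design_counterbalance_and_validation():
    design = ra.make_design(26, seed=0)
    assert len(design) == 260
    assert design.groupby("listener").size().eq(10).all()
    assert set(design["order"]) == {"NL", "LN"}
    # order not aliased to reader
    assert design.groupby("reader")["order"].nunique().eq(2).all()
    per_cond = design.groupby(["listener", "condition"]).size()
    assert per_cond.eq(5).all()
    # each listener's 10 texts are distinct
    assert design.groupby("listener")["text"].nunique().eq(10).all()
    with pytest.raises(ParameterError):
        ra.make_design(0)


def test_experiment_bundle_counts_small():
    design = ra.make_design(2, n_texts_per_condition=2, seed=1)
    from dataclasses import replace

    fast = {
        "F": replace(ra.FEMALE_READER, trial_dur=20.0, fs=50.0),
        "M": replace(ra.MALE_READER, trial_dur=20.0, fs=50.0),
    }
    bundle = ra.simulate_experiment(
        design, reader_params=fast,
        listener_params=replace(ra.DEFAULT_LISTENER, fs=50.0), seed=1,
    )
    assert bundle.n_listener_trials == 8
    assert set(bundle.vc) == set(design["listener"]) | set(design["reader"])
    again = ra.simulate_experiment(
        design, reader_params=fast,
        listener_params=replace(ra.DEFAULT_LISTENER, fs=50.0), seed=1,
    )
    k = next(iter(bundle.listener_trials))
    assert np.array_equal(
        bundle.listener_trials[k][0].ribcage, again.listener_trials[k][0].ribcage
    )


def test_invalid_params_rejected():
    with pytest.raises(ParameterError):
        ra.ReaderSimParams(inhal_frac=0.7)
    with pytest.raises(ParameterError):
        ra.ListenerSimParams(coupling_mode="magnetic")
    with pytest.raises(ParameterError):
        ra.ListenerSimParams(coupling_phase=1.0)
    with pytest.raises(ParameterError):
        ra.ListenerSimParams(artifact_rate=-1.0)


def test_trial_rng_is_stable_and_key_sensitive():
    a = trial_rng(1, "listener", "S01").integers(1 << 30)
    b = trial_rng(1, "listener", "S01").integers(1 << 30)
    c = trial_rng(1, "listener", "S02").integers(1 << 30)
    assert a == b and a != c


def test_parameter_table_structure():
    tab = ra.simulate_parameter_table(n_listeners=4, condition_effect_dur=-0.5, seed=3)
    assert {"listener", "text", "condition", "order", "durC", "ampI"} <= set(tab.columns)
    means = tab.groupby("condition")["durC"].mean()
    assert means["L"] < means["N"]
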