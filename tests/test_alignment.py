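"""posI computation, surrogate re-pairing and KS comparisons."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

import respalign as ra
from oracles import sup_ecdf_distance
from respalign.alignment import derangement, posI_observations, reflected_kde
from respalign.types import ContractError, LabelError, ParameterError


class TestAlign:
    def _cycle(self, onset):
        return ra.BreathingCycle(onset_t=onset, inhal_offset_t=onset + 1.0,
                                 next_onset_t=onset + 3.0, ampI=10.0)

    def test_shift_by_own_onset_labels(self):
        lis, red = ra.align_to_speech_onset(
            [self._cycle(5.0)], [self._cycle(4.0)], 2.0, 1.5
        )
        assert lis[0].onset_t == pytest.approx(3.0)
        assert red[0].onset_t == pytest.approx(2.5)

    def test_zero_onset_is_identity(self):
        lis, _ = ra.align_to_speech_onset([self._cycle(5.0)], [], 0.0, 0.0)
        assert lis[0].onset_t == 5.0

    def test_missing_label_rejected(self):
        with pytest.raises(LabelError):
            ra.align_to_speech_onset([], [], None, 1.0)


class TestPosI:
    def test_worked_example_15_percent(self):
        out = ra.compute_posI([10.6], [10.0, 14.0])
        assert out["posI"].iloc[0] == pytest.approx(0.15)

    def test_half_open_convention(self):
        out = ra.compute_posI([10.0, 12.0], [10.0, 14.0])
        assert list(out["posI"]) == pytest.approx([0.0, 0.5])

    def test_onsets_outside_span_dropped(self):
        out = ra.compute_posI([5.0, 14.0, 20.0], [10.0, 14.0])
        assert len(out) == 0

    def test_first_cycle_flagged(self):
        out = ra.compute_posI([11.0, 12.0], [10.0, 14.0])
        assert list(out["first_cycle"]) == [True, False]

    def test_range_invariant(self):
        rng = np.random.default_rng(3)
        reader = np.cumsum(rng.uniform(2, 6, 50))
        listener = rng.uniform(reader[0], reader[-1], 500)
        out = ra.compute_posI(listener, reader)
        assert ((out["posI"] >= 0) & (out["posI"] < 1)).all()

    def test_empty_reader_rejected(self):
        with pytest.raises(ContractError):
            ra.compute_posI([1.0], [5.0])


class TestKS:
    def test_identical_samples(self):
        r = ra.ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.D == 0.0 and r.p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        r = ra.ks_two_sample([0.0] * 10, [1.0] * 10)
        assert r.D == 1.0 and r.p < 1e-4

    def test_matches_brute_force_sup_ecdf(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            a = rng.normal(size=int(rng.integers(5, 60)))
            b = rng.normal(loc=rng.uniform(-1, 1), size=int(rng.integers(5, 60)))
            assert ra.ks_two_sample(a, b).D == pytest.approx(
                sup_ecdf_distance(a, b), abs=1e-12
            )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=40), rng.normal(0.5, 1.2, size=55)
        d0 = ra.ks_two_sample(a, b).D
        f = lambda x: np.exp(0.7 * x) + 3.0
        assert ra.ks_two_sample(f(a), f(b)).D == pytest.approx(d0, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ContractError):
            ra.ks_two_sample([], [1.0])


class TestDerangement:
    def test_no_fixed_points(self):
        rng = np.random.default_rng(0)
        items = list("abcde")
        for _ in range(50):
            out = derangement(items, rng)
            assert sorted(out) == sorted(items)
            assert all(a != b for a, b in zip(items, out))

    def test_two_items_swap(self):
        rng = np.random.default_rng(0)
        assert derangement([1, 2], rng) == [2, 1]

    def test_single_item_rejected(self):
        with pytest.raises(ParameterError):
            derangement([1], np.random.default_rng(0))


@pytest.fixture(scope="module")
def phase_locked_study():
    """Small study with listeners phase-locked at 0.15 (jitter sd 0.03),
    posI computed from ground-truth onsets."""
    listener_params = replace(
        ra.DEFAULT_LISTENER, coupling_mode="phase_locked",
        coupling_phase=0.15, coupling_jitter_sd=0.03, fs=50.0,
    )
    reader_params = replace(ra.FEMALE_READER, trial_dur=120.0, fs=50.0)
    design = ra.make_design(4, readers=("F",), n_texts_per_condition=5, seed=5)
    reader_onsets = {}
    listener_onsets = {}
    for reader, text, cond in (
        design[["reader", "text", "condition"]].drop_duplicates().itertuples(index=False)
    ):
        _, labels, truth = ra.simulate_reader_trial(reader_params, text, cond,
                                                    seed=5, reader_id=reader)
        reader_onsets[(reader, text, cond)] = (
            np.asarray(truth.onsets) - labels.speech_onset_s
        )
    for row in design.itertuples(index=False):
        key = (row.reader, row.text, row.condition)
        _, labels, truth = ra.simulate_reader_trial(reader_params, row.text,
                                                    row.condition, seed=5,
                                                    reader_id=row.reader)
        _, lt = ra.simulate_listener_trial(
            listener_params, truth, row.condition, seed=5,
            listener_id=row.listener, trial_id=f"{row.listener}_{row.trial_index}",
        )
        listener_onsets[(row.listener, int(row.trial_index))] = (
            np.asarray(lt.onsets) - labels.speech_onset_s
        )
    original = posI_observations(design, listener_onsets, reader_onsets)
    surrogate = ra.random_association(design, listener_onsets, reader_onsets,
                                      seed=5, n_draws=1)
    return design, listener_onsets, reader_onsets, original, surrogate


class TestSurrogate:
    def test_no_trial_keeps_its_own_text(self, phase_locked_study):
        _, _, _, _, surrogate = phase_locked_study
        assert (surrogate["text_id"] != surrogate["own_text"]).all()

    def test_same_condition_pairing(self, phase_locked_study):
        design, _, _, _, surrogate = phase_locked_study
        valid = set(map(tuple, design[["condition", "text"]].drop_duplicates().values))
        assert set(map(tuple, surrogate[["condition", "text_id"]].values)) <= valid

    def test_listener_cycle_multiset_preserved(self, phase_locked_study):
        """Surrogates change only the reader side: every surrogate
        observation uses an unmodified listener onset from its own trial,
        and the listener-onset inputs are not mutated."""
        design, listener_onsets, reader_onsets, _, surrogate = phase_locked_study
        before = {k: v.copy() for k, v in listener_onsets.items()}
        ra.random_association(design, listener_onsets, reader_onsets, seed=99)
        for k in before:
            assert np.array_equal(listener_onsets[k], before[k])
        for (lis, ti), grp in surrogate.groupby(["listener_id", "trial_index"]):
            own = set(np.round(listener_onsets[(lis, int(ti))], 12))
            assert set(np.round(grp["listener_onset_t"], 12)) <= own

    def test_same_seed_same_pairing(self, phase_locked_study):
        design, listener_onsets, reader_onsets, _, surrogate = phase_locked_study
        again = ra.random_association(design, listener_onsets, reader_onsets,
                                      seed=5, n_draws=1)
        pd.testing.assert_frame_equal(surrogate, again)

    def test_single_text_condition_rejected(self, phase_locked_study):
        design, listener_onsets, reader_onsets, _, _ = phase_locked_study
        single = design[design["trial_index"].isin([1, 6])]
        with pytest.raises(ParameterError):
            ra.random_association(single, listener_onsets, reader_onsets, seed=1)


class TestCouplingRecovery:
    def test_phase_locked_mode_and_ks(self, phase_locked_study):
        _, _, _, original, surrogate = phase_locked_study
        pos = original["posI"].to_numpy()
        assert len(pos) >= 500
        assert ra.posI_mode(pos) == pytest.approx(0.15, abs=0.05)
        ks = ra.ks_two_sample(pos, surrogate["posI"].to_numpy())
        assert ks.p < 1e-3

    def test_surrogate_flat_original_peaked(self, phase_locked_study):
        _, _, _, original, surrogate = phase_locked_study
        p_orig = sstats.kstest(original["posI"], "uniform").pvalue
        p_surr = sstats.kstest(surrogate["posI"], "uniform").pvalue
        assert p_orig < 1e-6  # locked phases are far from uniform
        assert p_surr > p_orig


class TestReport:
    def test_strata_and_first_cycle_subset(self, phase_locked_study):
        _, _, _, original, surrogate = phase_locked_study
        obs = pd.concat([original, surrogate], ignore_index=True)
        rep_all = ra.posI_report(obs, subset="all")
        assert set(rep_all["condition"]) == {"N", "L"}
        assert (rep_all["n_original"] > 0).all()
        rep_first = ra.posI_report(obs, subset="first_cycle")
        assert (rep_first["n_original"] < rep_all["n_original"]).all()

    def test_single_observation_stratum_skips_ks(self):
        obs = pd.DataFrame(
            dict(posI=[0.4], first_cycle=[True], condition=["N"],
                 reader=["F"], pairing=["original"])
        )
        rep = ra.posI_report(obs)
        assert len(rep) == 1 and np.isnan(rep["ks_p"].iloc[0])

    def test_kde_integrates_to_one(self):
        rng = np.random.default_rng(2)
        grid, dens = reflected_kde(rng.uniform(0, 1, 300))
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=0.03)
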