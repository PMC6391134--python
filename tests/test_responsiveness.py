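import numpy as np
import pandas as pd
import pytest

from isidecode import (
    Session,
    SessionSpec,
    SpikeTrain,
    Trial,
    classify_ramping,
    evoked_zscore,
    make_session,
    ramp_index,
    receptive_field,
    selectivity_indices,
    tone_modulation_test,
    uniplexing_projection,
)
from isidecode.responsiveness import bootstrap_ramp_indices
from isidecode.simulate import homogeneous_cell, ramping_cell


def _count_session(tone_counts, pre_counts, end=1.0, freqs=None):
    """Session whose unit fires `pre_counts[i]` spikes in [-0.1, 0) and
    `tone_counts[i]` in [0, 0.1) on trial i (plus baseline coverage)."""
    trials, spikes = [], []
    for i, (tc, pc) in enumerate(zip(tone_counts, pre_counts)):
        freq = None if freqs is None else freqs[i]
        trials.append(
            Trial(f"t{i}", "target", "go", response_time=end, frequency_khz=freq)
        )
        t = np.concatenate(
            [
                np.linspace(-0.29, -0.11, 4),  # fills the two earlier baselines
                np.linspace(-0.099, -0.001, pc) if pc else [],
                np.linspace(0.001, 0.099, tc) if tc else [],
                [0.12, 0.18],  # post-tone window matches the 2-spike baselines
                np.linspace(0.25, end - 0.01, 3),
            ]
        )
        spikes.append(SpikeTrain("u0", f"t{i}", np.sort(t)))
    return Session(trials, spikes)


class TestToneModulation:
    def test_zero_changes_are_ncr(self):
        sess = _count_session([2] * 40, [2] * 40)
        tone_mod, cov = tone_modulation_test(sess, "u0", n_boot=500, seed=0)
        assert not tone_mod
        assert cov["tone"] >= 0.95

    def test_large_evoked_change_is_responsive(self):
        sess = _count_session([4] * 40, [2] * 40)
        tone_mod, cov = tone_modulation_test(sess, "u0", n_boot=500, seed=0)
        assert tone_mod
        assert cov["tone"] < 0.95

    def test_requires_pre_trial_retention(self, tiny_session):
        tiny_session.pre_trial_bound = 0.1
        with pytest.raises(ValueError, match="pre-trial"):
            tone_modulation_test(tiny_session, "u0")

    def test_agrees_with_reference_bootstrap(self):
        # independent plain-loop re-implementation of the subsampled
        # bootstrap decision, compared over several seeded datasets
        rng = np.random.default_rng(0)
        for seed in range(5):
            r = np.random.default_rng(seed)
            n = 60
            tone = r.poisson(2.2, n)
            pre = r.poisson(2.0, n)
            sess = _count_session(tone, pre)
            got, _ = tone_modulation_test(sess, "u0", n_boot=2000, seed=seed)

            changes = []
            for tc, pc in zip(tone, pre):
                for b in (2, 2, pc):  # three baselines as constructed
                    changes.append(tc - b)
            changes = np.asarray(changes, float)
            m = int(np.floor(0.9 * changes.size))
            means = []
            for _ in range(2000):
                means.append(
                    changes[rng.choice(changes.size, m, replace=False)].mean()
                )
            cov = np.mean(np.abs(means) <= 0.1)
            # post-tone window holds 2 spikes by construction
            post_changes = []
            for pc in pre:
                for b in (2, 2, pc):
                    post_changes.append(2 - b)
            post_changes = np.asarray(post_changes, float)
            pmeans = [
                post_changes[rng.choice(post_changes.size, int(0.9 * post_changes.size), replace=False)].mean()
                for _ in range(2000)
            ]
            pcov = np.mean(np.abs(pmeans) <= 0.1)
            expected = not (cov >= 0.95 and pcov >= 0.95)
            assert got == expected


class TestRampIndex:
    def test_flat_cell_near_zero(self):
        sess, _ = make_session(
            SessionSpec(n_trials=200, cells=[homogeneous_cell(10.0)], seed=1)
        )
        ri = ramp_index(sess, "u0")
        assert abs(ri) < 4.0  # max-of-slopes has a small positive bias

    def test_recovers_positive_slope(self):
        sess, _ = make_session(
            SessionSpec(n_trials=400, cells=[ramping_cell(10.0, base_rate=12.0)], seed=10)
        )
        ri = ramp_index(sess, "u0")
        assert ri == pytest.approx(10.0, rel=0.3)

    def test_negative_slope_gives_negative_index(self):
        # taking the max over sliding-window slopes biases the index
        # upward by about one window-noise sigma, so the magnitude check
        # is loose at this trial count
        sess, _ = make_session(
            SessionSpec(n_trials=800, cells=[ramping_cell(-5.0, base_rate=12.0)], seed=5)
        )
        ri = ramp_index(sess, "u0")
        assert -7.0 < ri < -2.0

    def test_needs_trials(self, tiny_session):
        with pytest.raises(ValueError):
            ramp_index(tiny_session, "u0", trial_ids=["a"])


class TestClassifyRamping:
    def test_flat_not_ramping(self):
        samples = np.random.default_rng(0).normal(0.0, 0.2, 500)
        assert not classify_ramping(samples, rate_baseline=10.0, r_best=0.9)

    def test_full_change_with_high_r_is_ramping(self):
        samples = np.full(500, 20.0)  # 20 (sp/s)/s * 0.5 s = 10 sp/s change on 10 Hz
        assert classify_ramping(samples, rate_baseline=10.0, r_best=0.9)

    def test_forty_percent_change_is_not(self):
        samples = np.full(500, 8.0)  # 8 * 0.5 / 10 = 40% < 50%
        assert not classify_ramping(samples, rate_baseline=10.0, r_best=0.9)

    def test_low_r_vetoes(self):
        samples = np.full(500, 20.0)
        assert not classify_ramping(samples, rate_baseline=10.0, r_best=0.3)

    def test_bootstrap_pipeline_on_ramping_cell(self):
        sess, _ = make_session(
            SessionSpec(n_trials=150, cells=[ramping_cell(15.0, 8.0)], seed=2)
        )
        samples, r_best, baseline = bootstrap_ramp_indices(sess, "u0", n_boot=100, seed=0)
        assert classify_ramping(samples, baseline, r_best=r_best)


class TestEvokedZscore:
    def test_symmetric_changes_zero(self):
        sess = _count_session([3, 1], [1, 3])
        assert evoked_zscore(sess, "u0") == pytest.approx(0.0)

    def test_constant_change_absent(self):
        sess = _count_session([3, 3], [2, 2])
        assert evoked_zscore(sess, "u0") is None

    def test_matches_manual_computation(self):
        rng = np.random.default_rng(5)
        tone = rng.poisson(2.5, 100)
        pre = rng.poisson(2.0, 100)
        sess = _count_session(tone, pre)
        changes = tone.astype(float) - pre
        expected = changes.mean() / changes.std(ddof=1)
        assert evoked_zscore(sess, "u0") == pytest.approx(expected)


class TestReceptiveField:
    def _tuning_session(self, freqs, amplitudes, reps=4):
        tone_counts, pre_counts, trial_freqs = [], [], []
        for f, a in zip(freqs, amplitudes):
            for r in range(reps):
                # spread the amplitude over trials so the mean change is a
                base = int(a)
                extra = 1 if (a - base) * reps > r else 0
                tone_counts.append(base + extra)
                pre_counts.append(0)
                trial_freqs.append(f)
        return _count_session(tone_counts, pre_counts, freqs=trial_freqs)

    def test_single_responsive_frequency(self):
        freqs = [1, 2, 4, 8, 16]
        sess = self._tuning_session(freqs, [0, 0, 5, 0, 0])
        best, bw = receptive_field(sess, "u0")
        assert best == 4

    def test_flat_tuning_spans_range(self):
        freqs = [1, 2, 4, 8, 16]
        sess = self._tuning_session(freqs, [3, 3, 3, 3, 3])
        best, bw = receptive_field(sess, "u0")
        assert bw == pytest.approx(np.log2(16) - np.log2(1))

    def test_gaussian_tuning_fwhm(self):
        freqs = [0.5 * 2**k for k in range(7)]  # 0.5..32 kHz, octave spacing
        center = np.log2(4.0)
        amps = [10 * np.exp(-0.5 * (np.log2(f) - center) ** 2) for f in freqs]
        sess = self._tuning_session(freqs, amps, reps=10)
        best, bw = receptive_field(sess, "u0")
        assert best == pytest.approx(4.0)
        assert bw == pytest.approx(2.355, rel=0.2)

    def test_requires_frequency_labels(self, tiny_session):
        with pytest.raises(ValueError, match="frequency"):
            receptive_field(tiny_session, "u0")


class TestSelectivity:
    def _table(self, n, rng, stim_driven=True):
        s = rng.random(n) < 0.5
        c = np.where(rng.random(n) < 0.8, s, ~s)  # correlated choice
        drive = s if stim_driven else c
        p_stim = 1 / (1 + np.exp(-(2.0 * np.where(drive, 1, -1) + rng.normal(0, 0.5, n))))
        p_choice = 1 / (1 + np.exp(-(2.0 * np.where(c, 1, -1) + rng.normal(0, 0.5, n))))
        return pd.DataFrame(
            {
                "stimulus": np.where(s, "target", "non-target"),
                "choice": np.where(c, "go", "no-go"),
                "stimulus_posterior": p_stim,
                "choice_posterior": p_choice,
            }
        )

    def test_stimulus_driven_probabilities(self):
        rep = selectivity_indices(self._table(400, np.random.default_rng(0)))
        assert rep.stimulus_selectivity_index > 0
        assert rep.choice_selectivity_index > 0  # choice posterior is choice-driven
        assert rep.multiplexed

    def test_choice_driven_stimulus_probability_not_stimulus_selective(self):
        rep = selectivity_indices(
            self._table(400, np.random.default_rng(1), stim_driven=False)
        )
        assert rep.stimulus_selectivity_index <= 0

    def test_equal_performance_zero_uniplexing(self):
        rng = np.random.default_rng(2)
        df = self._table(200, rng)
        df["choice_posterior"] = df["stimulus_posterior"].where(
            df["choice"].eq("go").eq(df["stimulus"].eq("target")),
            1 - df["stimulus_posterior"],
        )
        rep = selectivity_indices(df)
        assert rep.decoding_uniplexing_index == pytest.approx(0.0, abs=1e-12)

    def test_needs_twenty_trials(self):
        with pytest.raises(ValueError):
            selectivity_indices(self._table(10, np.random.default_rng(3)))

    def test_uniplexing_projection_orders_units(self):
        stim = np.array([2.0, 1.0, 0.0, -1.0, -2.0])
        choice = -0.8 * stim + 0.1
        proj = uniplexing_projection(stim, choice)
        assert np.all(np.diff(proj) < 0)  # decreasing with decreasing stim selectivity
        assert proj.mean() == pytest.approx(0.0, abs=1e-12)
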