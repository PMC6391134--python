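import numpy as np
import pytest

from isidecode import (
    SessionSpec,
    SpikeTrain,
    compare_to_null,
    cross_validated_decode,
    decode_ensemble,
    decode_trial,
    decode_unit,
    make_consensus_ensemble,
    make_session,
    predict_errors,
)
from isidecode.decoder import ISIDecoderBackend, PerformanceSummary
from isidecode.simulate import CellSpec, fig2c_cell, _DISTINCT_NONTARGET


class _Const:
    """Stub likelihood with a fixed density, or a per-ISI callable."""

    def __init__(self, value):
        self._value = value

    def evaluate_many(self, isis, finals):
        if callable(self._value):
            return np.array([self._value(i) for i in np.atleast_1d(isis)])
        return np.full(np.atleast_1d(isis).size, float(self._value))


class TestDecodeTrial:
    def test_prior_is_one_half(self):
        st = SpikeTrain("u", "t", np.empty(0))
        trace, result = decode_trial((_Const(1.0), _Const(1.0)), st, (0, 1))
        assert trace.posteriors.size == 0
        assert result.final_posterior_true == 0.5
        assert result.predicted is None

    def test_single_isi_three_to_one(self):
        st = SpikeTrain("u", "t", np.array([0.1, 0.2]))
        _, result = decode_trial(
            (_Const(3.0), _Const(1.0)), st, (0, 1), true_label="target"
        )
        assert result.final_posterior_true == pytest.approx(0.75, abs=1e-12)
        assert result.predicted == "target"

    def test_sequential_equals_product(self):
        # final posterior must equal the normalized whole-trial product
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 2, 15))
        st = SpikeTrain("u", "t", times)
        fa = lambda isi: 0.5 + isi  # arbitrary positive densities
        fb = lambda isi: 1.2 - 0.4 * isi
        trace, result = decode_trial(
            (_Const(fa), _Const(fb)), st, (0, 2), true_label="target"
        )
        isis = np.diff(times)
        log_ratio = sum(np.log(fa(i)) - np.log(fb(i)) for i in isis)
        expected = 1.0 / (1.0 + np.exp(-log_ratio))
        assert result.final_posterior_true == pytest.approx(expected, abs=1e-12)

    def test_order_invariance(self):
        # the final posterior has product structure: any consumption order
        # of the same ISI multiset gives the same end-of-trial belief
        rng = np.random.default_rng(1)
        isis = rng.uniform(0.05, 0.3, 10)
        f = _Const(lambda i: 0.3 + 2 * i)
        g = _Const(lambda i: 1.0 - i)
        finals = []
        for perm_seed in (0, 1):
            order = np.random.default_rng(perm_seed).permutation(10)
            times = np.concatenate([[0.01], 0.01 + np.cumsum(isis[order])])
            st = SpikeTrain("u", "t", times)
            _, r = decode_trial((f, g), st, (0, 10), true_label="target")
            finals.append(r.final_posterior_true)
        assert finals[0] == pytest.approx(finals[1], abs=1e-12)

    def test_monotone_evidence(self):
        base = np.array([0.1, 0.2, 0.35])
        st1 = SpikeTrain("u", "t", base)
        st2 = SpikeTrain("u", "t", np.append(base, 0.5))
        pair = (_Const(2.0), _Const(1.0))
        _, r1 = decode_trial(pair, st1, (0, 1), true_label="target")
        _, r2 = decode_trial(pair, st2, (0, 1), true_label="target")
        assert r2.final_posterior_true > r1.final_posterior_true

    def test_posterior_normalized(self):
        st = SpikeTrain("u", "t", np.linspace(0.05, 0.9, 9))
        trace, _ = decode_trial((_Const(1.7), _Const(0.4)), st, (0, 1))
        assert np.all((trace.posteriors > 0) & (trace.posteriors < 1))


class TestCrossValidatedDecoding:
    def test_informative_cell_beats_chance(self, ncr_session):
        sess, _ = ncr_session
        s = decode_unit(sess, "u0", "stimulus", reps=2, seed=0)
        assert s.mean_performance > 0.6
        assert s.accuracy > 0.6

    def test_uninformative_cell_near_chance(self, flat_session):
        sess, _ = flat_session
        s = decode_unit(sess, "u0", "stimulus", reps=3, seed=0)
        assert abs(s.mean_performance - 0.5) < 0.08

    def test_fold_reduction_warns(self, ncr_session):
        sess, _ = ncr_session
        with pytest.warns(UserWarning, match="reducing folds"):
            s = decode_unit(sess, "u0", "stimulus", folds=50, reps=1, seed=0)
        assert s.folds < 50

    def test_seed_reproducibility(self, ncr_session):
        sess, _ = ncr_session
        a = decode_unit(sess, "u0", "choice", reps=2, seed=42)
        b = decode_unit(sess, "u0", "choice", reps=2, seed=42)
        np.testing.assert_array_equal(a.performance_reps, b.performance_reps)

    def test_ensemble_of_one_matches_single_unit(self, ncr_session):
        sess, _ = ncr_session
        a = decode_unit(sess, "u0", "stimulus", reps=2, seed=7)
        b = decode_ensemble(sess, ["u0"], "stimulus", reps=2, seed=7)
        np.testing.assert_array_equal(a.performance_reps, b.performance_reps)

    def test_opposite_llr_members_cancel(self, ncr_session):
        # two members with exactly opposite LLRs observing the same ISI
        # stream: the per-ISI likelihood ratios are reciprocal, so the
        # shared posterior products cancel back to the 50% prior
        sess, _ = ncr_session
        sess.assign_windows()
        backend = ISIDecoderBackend()
        train_ids = [t.trial_id for t in sess.trials[:-1]]
        ma, mb = backend.fit(sess, "u0", train_ids, "stimulus", np.random.default_rng(0))
        tid = sess.trials[-1].trial_id
        _, d_fwd = backend.trial_updates((ma, mb), sess, "u0", tid)
        _, d_rev = backend.trial_updates((mb, ma), sess, "u0", tid)
        assert d_fwd.size > 0
        total = d_fwd.sum() + d_rev.sum()
        posterior = 1.0 / (1.0 + np.exp(-total))
        assert posterior == pytest.approx(0.5, abs=1e-12)

    def test_two_informative_copies_do_not_hurt(self):
        sess, _ = make_consensus_ensemble(
            "identical", 2, spec=SessionSpec(n_trials=60, seed=6)
        )
        single = decode_unit(sess, "u0", "stimulus", reps=2, seed=1)
        ens = decode_ensemble(sess, ["u0", "u1"], "stimulus", reps=2, seed=1)
        assert ens.mean_performance >= single.mean_performance - 0.02

    def test_trial_table_contents(self, ncr_session):
        sess, _ = ncr_session
        _, table = cross_validated_decode(
            sess, ["u0"], "stimulus", ISIDecoderBackend(), reps=1, seed=0
        )
        assert len(table) == len(sess.trials)
        assert set(table.columns) >= {
            "trial_id", "variable", "final_posterior_true", "predicted", "true_label",
        }
        assert table["final_posterior_true"].between(0, 1).all()


class TestErrorPrediction:
    def test_choice_consistent_errors_predicted(self):
        # choice-coding cell: error trials carry choice-consistent (not
        # stimulus-consistent) ISI statistics, so decoded-choice mismatches
        # flag them above chance
        cell = CellSpec(
            cell_kind="choice_coding",
            isi_params={
                "go": fig2c_cell().isi_params["target"],
                "no-go": fig2c_cell().isi_params["non-target"],
            },
        )
        sess, _ = make_session(
            SessionSpec(n_trials=80, hit_rate=0.8, false_alarm_rate=0.2,
                        cells=[cell], seed=9)
        )
        perf = predict_errors(sess, ["u0"], reps=2, seed=0)
        assert perf is not None and perf > 0.55

    def test_all_correct_returns_absent(self):
        sess, _ = make_session(
            SessionSpec(n_trials=40, hit_rate=1.0, false_alarm_rate=0.0, seed=3)
        )
        with pytest.warns(UserWarning, match="no error trials"):
            assert predict_errors(sess, ["u0"], reps=1, seed=0) is None


class TestCompareToNull:
    def _summary(self, values):
        v = np.asarray(values, dtype=float)
        return PerformanceSummary("stimulus", v.mean(), v.mean(), v, v, 10, v.size, 10)

    def test_observed_above_all_nulls(self):
        p = compare_to_null(self._summary([0.9] * 5), np.full(1240, 0.5))
        assert p == pytest.approx(1 / 1241)

    def test_observed_below_all_nulls(self):
        p = compare_to_null(self._summary([0.3] * 5), np.full(100, 0.5))
        assert p == 1.0

    def test_null_under_null_is_roughly_uniform(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(200):
            obs = rng.normal(0.5, 0.02, 1)  # a single draw from the null itself
            nulls = rng.normal(0.5, 0.02, 300)
            ps.append(compare_to_null(self._summary(obs), nulls))
        ps = np.array(ps)
        # uniform on (0,1): mean ~ 0.5, spread over the full range
        assert abs(ps.mean() - 0.5) < 0.08
        assert (ps < 0.2).mean() == pytest.approx(0.2, abs=0.08)
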