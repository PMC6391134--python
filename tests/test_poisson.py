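from itertools import combinations

import numpy as np
import pytest
from scipy.special import gammaln
from sklearn.metrics import matthews_corrcoef

from isidecode import (
    RateModel,
    SessionSpec,
    SpikeTrain,
    decode_trial_poisson,
    decoder_mcc,
    fit_rate,
    make_session,
    max_mcc_fixed_margins,
    poisson_isi_density,
    poisson_loglik,
    poisson_loglik_isi_form,
)
from isidecode.decoder import DecodingResult
from isidecode.simulate import homogeneous_cell


def _const_rate(r, T=2.0, condition="target"):
    grid = np.arange(0.0, T + 1e-4, 0.001)
    return RateModel(condition, grid, np.full(grid.size, float(r)), 0.05, 10)


def _bumpy_rate(seed=0, T=2.0):
    rng = np.random.default_rng(seed)
    grid = np.arange(0.0, T + 1e-4, 0.001)
    rate = 5.0 + 4.0 * np.sin(2 * np.pi * grid / T * rng.uniform(0.5, 3)) ** 2
    return RateModel("target", grid, rate, 0.05, 10)


class TestPoissonLikelihood:
    def test_homogeneous_closed_form(self):
        r, T, n = 7.0, 2.0, 9
        st = SpikeTrain("u", "t", np.linspace(0.1, 1.9, n))
        ll = poisson_loglik(_const_rate(r, T), st, (0.0, T))
        expected = n * np.log(r) - r * T - gammaln(n + 1)
        assert ll == pytest.approx(expected, rel=1e-9)

    def test_empty_train_rate_doubling(self):
        st = SpikeTrain("u", "t", np.empty(0))
        T = 1.5
        ll1 = poisson_loglik(_const_rate(4.0, T), st, (0.0, T))
        ll2 = poisson_loglik(_const_rate(8.0, T), st, (0.0, T))
        assert ll1 - ll2 == pytest.approx(4.0 * T, rel=1e-9)

    def test_spike_time_form_equals_isi_factorized_form(self):
        rng = np.random.default_rng(1)
        model = _bumpy_rate(2)
        for _ in range(10):
            t = np.sort(rng.uniform(0.0, 2.0, rng.integers(0, 25)))
            st = SpikeTrain("u", "t", t)
            a = poisson_loglik(model, st, (0.0, 2.0))
            b = poisson_loglik_isi_form(model, st, (0.0, 2.0))
            assert a == pytest.approx(b, abs=1e-9)

    def test_true_rate_beats_flat_rate_on_average(self):
        # spikes thinned from a known r(t) are likelier under the true
        # rate than under a flat rate of equal total mass
        model = _bumpy_rate(3)
        flat_mass = model.integral(0.0, 2.0) / 2.0
        flat = _const_rate(flat_mass, 2.0)
        rng = np.random.default_rng(4)
        diffs = []
        for _ in range(500):
            r_max = model.rate.max()
            n = rng.poisson(r_max * 2.0)
            cand = np.sort(rng.uniform(0, 2.0, n))
            keep = rng.uniform(0, r_max, n) < model(cand)
            st = SpikeTrain("u", "t", cand[keep])
            diffs.append(
                poisson_loglik(model, st, (0, 2)) - poisson_loglik(flat, st, (0, 2))
            )
        assert np.mean(diffs) > 0


@pytest.fixture(scope="module")
def homog_session():
    # 400 trials so the "target" condition alone holds ~200 trials
    sess, _ = make_session(
        SessionSpec(n_trials=400, cells=[homogeneous_cell(10.0)], seed=77)
    )
    sess.assign_windows()
    return sess


class TestRateFitting:

    def test_recovers_homogeneous_rate(self, homog_session):
        ids = [t.trial_id for t in homog_session.trials]
        model = fit_rate(homog_session, "u0", "target", ids, rng=np.random.default_rng(0))
        # central 80% of the typical trial: beyond the median trial end only
        # a handful of long trials remain active and the estimate gets noisy
        t_med = np.median([t.effective_end for t in homog_session.trials])
        central = (model.grid > 0.1 * t_med) & (model.grid < 0.9 * t_med)
        assert np.all(np.abs(model.rate[central] - 10.0) / 10.0 < 0.15)

    def test_rate_integrates_to_mean_count(self, homog_session):
        ids = [
            t.trial_id for t in homog_session.trials if t.stimulus == "non-target"
        ]
        model = fit_rate(
            homog_session, "u0", "non-target", ids, rng=np.random.default_rng(1)
        )
        counts, integrals = [], []
        for tid in ids:
            t = homog_session.spike_train("u0", tid).spike_times
            end = homog_session.trial(tid).effective_end
            counts.append(np.count_nonzero((t >= 0) & (t < end)))
            integrals.append(model.integral(0.0, end))
        # trials have mixed lengths: the per-trial integral of the fitted
        # rate averages to the mean in-window spike count
        assert np.mean(integrals) == pytest.approx(np.mean(counts), rel=0.04)

    def test_scale_equivariance(self, homog_session):
        ids = [t.trial_id for t in homog_session.trials]
        m1 = fit_rate(homog_session, "u0", "target", ids, bandwidth=0.05)
        # doubling every spike doubles the rate pointwise at fixed bandwidth
        doubled = []
        eps = 1e-9  # keep times strictly increasing without crossing window edges
        for st in homog_session.spikes:
            doubled.append(SpikeTrain(st.unit_id, st.trial_id,
                                      np.sort(np.concatenate([st.spike_times,
                                                              st.spike_times + eps]))))
        from isidecode import Session
        sess2 = Session(homog_session.trials, doubled,
                        pre_trial_bound=homog_session.pre_trial_bound)
        m2 = fit_rate(sess2, "u0", "target", ids, bandwidth=0.05)
        np.testing.assert_allclose(m2.rate, 2 * m1.rate, rtol=1e-6)


class TestPoissonDecoding:
    def test_identical_models_give_half(self):
        st = SpikeTrain("u", "t", np.array([0.2, 0.5, 0.9]))
        m = _const_rate(5.0)
        r = decode_trial_poisson((m, m), st, (0.0, 2.0), true_label="target")
        assert r.final_posterior_true == pytest.approx(0.5)
        assert r.predicted is None


class TestPoissonISIDensity:
    def test_homogeneous_limit_is_exponential(self):
        # the windowed density carries a (span - ISI) truncation factor, so
        # the exponential limit needs a window much longer than 1/r
        r = 5.0
        isi, dens = poisson_isi_density(_const_rate(r, T=60.0), (0.0, 60.0), n_isi=6000)
        expected = r * np.exp(-r * isi)
        body = isi < 1.0  # away from the window-truncation tail
        rel = np.abs(dens[body] - expected[body]) / expected[body].max()
        assert rel.max() < 0.02

    def test_normalization(self):
        isi, dens = poisson_isi_density(_bumpy_rate(5), (0.2, 1.8))
        assert np.trapezoid(dens, isi) == pytest.approx(1.0, abs=1e-3)


def _results(correct, prefix):
    out = []
    for i, c in enumerate(correct):
        out.append(
            DecodingResult(f"t{i}", "stimulus", 0.7 if c else 0.3,
                           "target" if c else "non-target", "target")
        )
    return out


class TestDecoderAgreement:
    def test_identical_correctness_gives_plus_one(self):
        c = [True, True, False, True, False, False, True]
        agr = decoder_mcc(_results(c, "a"), _results(c, "b"))
        assert agr.mcc == pytest.approx(1.0)
        assert agr.rescaled_mcc == pytest.approx(1.0)

    def test_complementary_correctness_gives_minus_one(self):
        c = [True, False, True, False]
        agr = decoder_mcc(_results(c, "a"), _results([not x for x in c], "b"))
        assert agr.mcc == pytest.approx(-1.0)

    def test_independent_correctness_near_zero(self):
        rng = np.random.default_rng(8)
        a = rng.random(10000) < 0.7
        b = rng.random(10000) < 0.7
        agr = decoder_mcc(_results(a, "a"), _results(b, "b"))
        assert abs(agr.mcc) < 0.03

    def test_matches_sklearn(self):
        rng = np.random.default_rng(9)
        a = rng.random(300) < 0.6
        b = (rng.random(300) < 0.3) ^ a
        agr = decoder_mcc(_results(a, "a"), _results(b, "b"))
        assert agr.mcc == pytest.approx(matthews_corrcoef(a, b), abs=1e-12)

    def test_degenerate_margin_absent(self):
        agr = decoder_mcc(_results([True] * 5, "a"), _results([True, False] * 2 + [True], "b"))
        assert agr.mcc is None and agr.rescaled_mcc is None

    @pytest.mark.parametrize("n,a,b", [(6, 2, 4), (8, 5, 5), (7, 1, 6), (8, 4, 2)])
    def test_max_mcc_matches_brute_force(self, n, a, b):
        # enumerate every placement of the two correct sets and take the
        # best achievable MCC with the margins held fixed
        best = -np.inf
        idx = list(range(n))
        for sa in combinations(idx, a):
            va = np.zeros(n, bool)
            va[list(sa)] = True
            for sb in combinations(idx, b):
                vb = np.zeros(n, bool)
                vb[list(sb)] = True
                n11 = int(np.sum(va & vb)); n10 = int(np.sum(va & ~vb))
                n01 = int(np.sum(~va & vb)); n00 = n - n11 - n10 - n01
                denom = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
                if denom:
                    best = max(best, (n11 * n00 - n10 * n01) / np.sqrt(denom))
        assert max_mcc_fixed_margins(a, b, n) == pytest.approx(best, abs=1e-12)
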