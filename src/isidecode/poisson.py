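"""Rate-modulated (inhomogeneous) Poisson baseline decoder.

The conventional rate-based alternative to ISI decoding: assuming spikes
are generated by a Poisson process with time-varying rate r_c(t) per
condition, the likelihood of a trial's spike train {t_1..t_n} is

    p({t_i} | c) = (1/n!) r_c(t_1) ... r_c(t_n) exp(-∫ r_c(t) dt)

with the rate estimated from the training-set PSTH by kernel density
estimation (10-fold cross-validated bandwidth) scaled to the mean spike
count per trial.  The same expression factorizes over ISIs with boundary
terms L_i, L_f for the silence before the first and after the last spike,
which also yields the ISI distribution the Poisson model predicts inside a
sliding window — the parametric point of comparison for the nonparametric
ISI densities.

Agreement between the ISI decoder and this baseline is summarized by the
Matthews correlation of their per-trial correctness, optionally rescaled
by the maximum correlation attainable at fixed marginal accuracies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .decoder import (
    DecodingResult,
    PerformanceSummary,
    VARIABLE_CONDITIONS,
    cross_validated_decode,
)
from .density import cv_bandwidth
from .session import Session, SpikeTrain
from scipy.special import ndtr

__all__ = [
    "RateModel",
    "DecoderAgreement",
    "fit_rate",
    "poisson_loglik",
    "poisson_loglik_isi_form",
    "decode_trial_poisson",
    "PoissonDecoderBackend",
    "decode_unit_poisson",
    "poisson_isi_density",
    "decoder_mcc",
    "max_mcc_fixed_margins",
]

RATE_FLOOR = 0.01  # spikes/s
RATE_DT = 0.001  # 1 ms rate grid
TIME_BANDWIDTH_GRID = np.geomspace(0.005, 0.5, 30)  # seconds


@dataclass
class RateModel:
    """Time-varying firing rate of one condition on a uniform 1 ms grid."""

    condition: str
    grid: np.ndarray
    rate: np.ndarray
    bandwidth: float
    n_training_trials: int

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.rate = np.maximum(np.asarray(self.rate, dtype=float), RATE_FLOOR)
        self._cum = np.concatenate(
            [[0.0], np.cumsum(0.5 * (self.rate[1:] + self.rate[:-1]) * np.diff(self.grid))]
        )

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        return np.interp(t, self.grid, self.rate)

    def integral(self, a: float, b: float) -> float:
        """∫_a^b r(t) dt by trapezoid on the grid (edge rate extended outside)."""
        return self._cum_at(b) - self._cum_at(a)

    def _cum_at(self, t: float) -> float:
        t0, t1 = self.grid[0], self.grid[-1]
        if t <= t0:
            return float(self.rate[0] * (t - t0))
        if t >= t1:
            return float(self._cum[-1] + self.rate[-1] * (t - t1))
        i = np.searchsorted(self.grid, t) - 1
        tt = self.grid[i]
        r_t = np.interp(t, self.grid, self.rate)
        return float(self._cum[i] + 0.5 * (self.rate[i] + r_t) * (t - tt))


def fit_rate(
    session: Session,
    unit: str,
    condition: str,
    training_trials: list[str],
    cv_folds: int = 10,
    bandwidth: float | None = None,
    dt: float = RATE_DT,
    rng: np.random.Generator | None = None,
) -> RateModel:
    """Estimate r_c(t) from the training PSTH.

    The pooled spike-time density (Gaussian KDE, CV bandwidth, mass
    renormalized to the trial span) is scaled by the mean spike count per
    trial, so the fitted rate integrates to the mean count; the rate is
    floored at 0.01 spikes/s.
    """
    session.assign_windows()
    variable = "stimulus" if condition in VARIABLE_CONDITIONS["stimulus"] else "choice"
    ids = [
        tid
        for tid in training_trials
        if (session.trial(tid).stimulus if variable == "stimulus" else session.trial(tid).choice)
        == condition
    ]
    if len(ids) < 2:
        raise ValueError(f"need >= 2 training trials of condition {condition!r}")
    ends = np.array([session.trial(t).effective_end for t in ids])
    t_max = float(ends.max())
    grid = np.arange(0.0, t_max + dt, dt)
    spikes = []
    for tid in ids:
        st = session.spike_train(unit, tid).spike_times
        end = session.trial(tid).effective_end
        spikes.append(st[(st >= 0.0) & (st < end)])
    spikes = np.concatenate(spikes) if spikes else np.empty(0)
    if spikes.size == 0:
        warnings.warn(f"no spikes for condition {condition!r}; flat floor rate")
        return RateModel(condition, grid, np.full(grid.size, RATE_FLOOR), 0.0, len(ids))
    rng = rng or np.random.default_rng()
    if bandwidth is None:
        if spikes.size >= 2:
            bandwidth = cv_bandwidth(spikes, TIME_BANDWIDTH_GRID, cv_folds, rng)
        else:
            bandwidth = float(TIME_BANDWIDTH_GRID[len(TIME_BANDWIDTH_GRID) // 2])
    # smoothed PSTH with varying trial lengths: each spike's kernel is
    # renormalized to the mass it keeps inside [0, t_max], and the summed
    # kernel density is divided by the number of trials still active at t,
    # so sum_trials int_0^end_i r(t) dt ~= total spike count
    z = ndtr((t_max - spikes) / bandwidth) - ndtr((0.0 - spikes) / bandwidth)
    z = np.where(z > 0, z, 1.0)
    diff = (grid[:, None] - spikes[None, :]) / bandwidth
    kernel_sum = (np.exp(-0.5 * diff**2) / z).sum(axis=1) / (
        bandwidth * np.sqrt(2 * np.pi)
    )
    n_active = np.maximum((ends[None, :] > grid[:, None]).sum(axis=1), 1)
    rate = np.maximum(kernel_sum / n_active, RATE_FLOOR)
    return RateModel(condition, grid, rate, float(bandwidth), len(ids))


def poisson_loglik(
    rate_model: RateModel, spike_train: SpikeTrain, window: tuple[float, float]
) -> float:
    """log p({t_i} | condition) under the rate-modulated Poisson model.

    Includes the -log n! permutation term; it is identical across
    conditions and cancels in likelihood ratios.
    """
    a, b = window
    t = spike_train.spike_times
    t = t[(t >= a) & (t < b)]
    ll = float(np.sum(np.log(rate_model(t)))) if t.size else 0.0
    ll -= rate_model.integral(a, b)
    ll -= float(gammaln(t.size + 1))
    return ll


def poisson_loglik_isi_form(
    rate_model: RateModel, spike_train: SpikeTrain, window: tuple[float, float]
) -> float:
    """The same likelihood factorized over ISIs with boundary terms.

    L_i covers the silence from trial start to the first spike (times the
    first-spike rate), each ISI term is the rate at the closing spike
    times the probability of silence in between, and L_f is the silence
    after the last spike.  Agrees with :func:`poisson_loglik` to numerical
    round-off; the decomposition is what defines the Poisson-predicted ISI
    distribution.
    """
    a, b = window
    t = spike_train.spike_times
    t = t[(t >= a) & (t < b)]
    n = t.size
    if n == 0:
        return -rate_model.integral(a, b)
    ll = np.log(float(rate_model(t[0]))) - rate_model.integral(a, float(t[0]))  # L_i
    for i in range(n - 1):
        ll += np.log(float(rate_model(t[i + 1]))) - rate_model.integral(
            float(t[i]), float(t[i + 1])
        )
    ll -= rate_model.integral(float(t[-1]), b)  # L_f
    ll -= float(gammaln(n + 1))
    return float(ll)


def decode_trial_poisson(
    rate_models: tuple[RateModel, RateModel],
    spike_train: SpikeTrain,
    window: tuple[float, float],
    variable: str = "stimulus",
    true_label: str | None = None,
) -> DecodingResult:
    """Posterior over the condition pair from the whole-trial Poisson likelihoods."""
    first, second = VARIABLE_CONDITIONS[variable]
    la = poisson_loglik(rate_models[0], spike_train, window)
    lb = poisson_loglik(rate_models[1], spike_train, window)
    p_first = float(0.5 * (1.0 + np.tanh(0.5 * (la - lb))))
    predicted = first if p_first > 0.5 else second if p_first < 0.5 else None
    p_true = p_first if (true_label is None or true_label == first) else 1.0 - p_first
    return DecodingResult(
        trial_id=spike_train.trial_id,
        variable=variable,
        final_posterior_true=p_true,
        predicted=predicted,
        true_label=true_label or "",
    )


class PoissonDecoderBackend:
    """Poisson-rate counterpart of the ISI backend for the shared CV engine.

    A trial contributes a single belief update at trial end equal to the
    whole-trial log-likelihood ratio (the n! terms cancel).
    """

    def __init__(self, cv_folds: int = 10, bandwidth: float | None = None):
        self.cv_folds = cv_folds
        self.bandwidth = bandwidth

    def fit(self, session, unit, training_ids, variable, rng):
        first, second = VARIABLE_CONDITIONS[variable]
        return (
            fit_rate(session, unit, first, training_ids, self.cv_folds, self.bandwidth, rng=rng),
            fit_rate(session, unit, second, training_ids, self.cv_folds, self.bandwidth, rng=rng),
        )

    def trial_updates(self, models, session, unit, trial_id):
        trial = session.trial(trial_id)
        st = session.spike_train(unit, trial_id)
        window = (0.0, trial.effective_end)
        la = poisson_loglik(models[0], st, window)
        lb = poisson_loglik(models[1], st, window)
        return np.array([trial.effective_end]), np.array([la - lb])


def decode_unit_poisson(
    session: Session,
    unit: str,
    variable: str = "stimulus",
    folds: int = 10,
    reps: int = 124,
    seed: int | None = None,
) -> PerformanceSummary:
    """Cross-validated Poisson-decoder performance, same protocol as the ISI decoder."""
    summary, _ = cross_validated_decode(
        session, [unit], variable, PoissonDecoderBackend(), folds=folds, reps=reps, seed=seed
    )
    return summary


def poisson_isi_density(
    rate_model: RateModel, window: tuple[float, float], n_isi: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """ISI distribution a rate-modulated Poisson process predicts in a window.

    p(ISI, t) = r(t) r(t+ISI) exp(-∫_t^{t+ISI} r), integrated over first-spike
    times t in [w_i, w_f - ISI] and normalized to unit mass over
    ISI in [0, w_f - w_i].  Returns (isi_grid, density).  In the
    homogeneous limit this reduces to the exponential density r e^{-r ISI}
    (up to window truncation).
    """
    wi, wf = window
    if not wf - wi > 0:
        raise ValueError("window must have positive length")
    span = wf - wi
    dt = RATE_DT
    t = np.arange(wi, wf + dt, dt)
    r = np.asarray(rate_model(t), dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (r[1:] + r[:-1]) * np.diff(t))])
    isi_grid = np.linspace(0.0, span, n_isi)
    dens = np.empty(n_isi)
    for k, isi in enumerate(isi_grid):
        m = int(round(isi / dt))
        if m >= t.size:
            dens[k] = 0.0
            continue
        n_t = t.size - m  # first-spike times with t + ISI inside the window
        integrand = r[:n_t] * r[m : m + n_t] * np.exp(-(cum[m : m + n_t] - cum[:n_t]))
        dens[k] = np.trapezoid(integrand, t[:n_t]) if n_t > 1 else 0.0
    z = np.trapezoid(dens, isi_grid)
    if z > 0:
        dens /= z
    return isi_grid, dens


@dataclass
class DecoderAgreement:
    """Matthews correlation between two decoders' per-trial correctness."""

    mcc: float | None
    rescaled_mcc: float | None
    n_trials: int


def _mcc_from_table(n11: int, n10: int, n01: int, n00: int) -> float | None:
    denom = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    if denom == 0:
        return None
    return (n11 * n00 - n10 * n01) / np.sqrt(denom)


def max_mcc_fixed_margins(a: int, b: int, n: int) -> float | None:
    """Maximum MCC over 2x2 tables with fixed marginal correct-counts a, b.

    Scans every feasible overlap of the two correct sets; equals the
    brute-force enumeration optimum.
    """
    lo, hi = max(0, a + b - n), min(a, b)
    best = None
    for k in range(lo, hi + 1):
        m = _mcc_from_table(k, a - k, b - k, n - a - b + k)
        if m is not None and (best is None or m > best):
            best = m
    return best


def decoder_mcc(
    results_a: list[DecodingResult], results_b: list[DecodingResult]
) -> DecoderAgreement:
    """Agreement of two decoders on the same trials.

    +1: correct on exactly the same trials; -1: correct on complementary
    trials; ~0: unrelated.  ``rescaled_mcc`` divides by the maximum MCC
    attainable with each decoder's accuracy held fixed.  Degenerate
    marginals (a decoder always right or always wrong) leave both absent.
    """
    ra = {r.trial_id: r for r in results_a}
    rb = {r.trial_id: r for r in results_b}
    common = sorted(set(ra) & set(rb))
    if not common:
        raise ValueError("no shared trials")
    ca = np.array([ra[t].predicted == ra[t].true_label for t in common])
    cb = np.array([rb[t].predicted == rb[t].true_label for t in common])
    n = len(common)
    n11 = int(np.sum(ca & cb))
    n10 = int(np.sum(ca & ~cb))
    n01 = int(np.sum(~ca & cb))
    n00 = n - n11 - n10 - n01
    mcc = _mcc_from_table(n11, n10, n01, n00)
    if mcc is None:
        return DecoderAgreement(None, None, n)
    m_max = max_mcc_fixed_margins(int(ca.sum()), int(cb.sum()), n)
    rescaled = mcc / m_max if m_max else None
    return DecoderAgreement(float(mcc), rescaled, n)
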