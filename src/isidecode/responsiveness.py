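"""Classical vs. non-classical responsiveness statistics.

A unit is *classically responsive* when its trial-averaged rate shows
either significant tone-evoked modulation or ramping toward the
behavioral response; a *non-classically responsive* (NCR) unit shows
neither.  Tone modulation is tested conservatively with a subsampled
bootstrap on per-trial spike-count changes (tone and post-tone 100 ms
windows against three sequential 100 ms pre-onset baselines): the cell is
sensory NCR when 95% of 5000 subsampled means stay within ±0.1 spikes for
both test windows.  Ramping is the maximum slope of a linear regression of
the response-aligned rate in a 500 ms sliding window starting 850 ms
before the response (the "ramp index"); a cell ramps when the implied
rate change exceeds 50% of its mean rate under subsampled bootstrapping
and the best window's Pearson r exceeds 0.5.

Also here: the evoked z-score, receptive-field summaries (best frequency,
half-height bandwidth on a log2 axis), and the regression-based
stimulus/choice selectivity indices used to verify multiplexing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .session import Session

__all__ = [
    "ResponsivenessReport",
    "SelectivityReport",
    "tone_modulation_test",
    "ramp_index",
    "bootstrap_ramp_indices",
    "classify_ramping",
    "classify_unit",
    "evoked_zscore",
    "receptive_field",
    "selectivity_indices",
    "uniplexing_projection",
]

BASELINE_WINDOWS = ((-0.3, -0.2), (-0.2, -0.1), (-0.1, 0.0))
TONE_WINDOW = (0.0, 0.1)
POST_TONE_WINDOW = (0.1, 0.2)


def _count(spike_times: np.ndarray, window: tuple[float, float]) -> int:
    return int(np.count_nonzero((spike_times >= window[0]) & (spike_times < window[1])))


def _subsampled_means(
    changes: np.ndarray, n_boot: int, subsample: float, rng: np.random.Generator
) -> np.ndarray:
    n = changes.size
    m = max(1, int(np.floor(subsample * n)))
    # one argsort per rep of a uniform matrix = sampling without replacement
    order = np.argsort(rng.random((n_boot, n)), axis=1)[:, :m]
    return changes[order].mean(axis=1)


def tone_modulation_test(
    session: Session,
    unit: str,
    n_boot: int = 5000,
    subsample: float = 0.9,
    band: float = 0.1,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[bool, dict[str, float]]:
    """Subsampled-bootstrap test for tone-evoked spike-count modulation.

    Returns ``(tone_modulated, coverage)`` where coverage maps each test
    window to the fraction of subsampled means inside ±``band`` spikes.
    The unit is sensory NCR (``tone_modulated=False``) only when both the
    tone and post-tone windows are within-band at the 1-alpha level.
    """
    if session.pre_trial_bound < 0.3 - 1e-9:
        raise ValueError(
            "tone-modulation baselines need spikes retained >= 0.3 s before onset; "
            "re-read the session with a wider pre-trial bound"
        )
    rng = np.random.default_rng(seed)
    changes = {"tone": [], "post_tone": []}
    any_pre = False
    for trial in session.trials:
        t = session.spike_train(unit, trial.trial_id).spike_times
        if t.size and t[0] < 0:
            any_pre = True
        base = [_count(t, w) for w in BASELINE_WINDOWS]
        for name, win in (("tone", TONE_WINDOW), ("post_tone", POST_TONE_WINDOW)):
            c = _count(t, win)
            changes[name].extend(c - b for b in base)
    if not session.trials:
        raise ValueError("session has no trials")
    if not any_pre:
        warnings.warn(f"unit {unit!r}: no pre-onset spikes observed; baselines are zero")
    coverage = {}
    for name, vals in changes.items():
        means = _subsampled_means(np.asarray(vals, dtype=float), n_boot, subsample, rng)
        coverage[name] = float(np.mean((means >= -band) & (means <= band)))
    ncr = all(cov >= 1.0 - alpha for cov in coverage.values())
    return (not ncr), coverage


def _response_aligned_rate(
    session: Session,
    unit: str,
    trial_ids: list[str] | None = None,
    bin_s: float = 0.05,
    span: float = 0.85,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged firing rate in ``bin_s`` bins over the ``span`` seconds
    before the behavioral response (bin centers are response-aligned,
    negative before the response)."""
    session.assign_windows()
    ids = trial_ids if trial_ids is not None else [t.trial_id for t in session.trials]
    if len(ids) < 1:
        raise ValueError("no trials")
    n_bins = int(round(span / bin_s))
    edges = np.linspace(-span, 0.0, n_bins + 1)
    counts = np.zeros(n_bins)
    short = 0
    for tid in ids:
        trial = session.trial(tid)
        resp = trial.response_time if trial.response_time is not None else trial.effective_end
        if resp + session.pre_trial_bound < span:
            short += 1
        t = session.spike_train(unit, tid).spike_times - resp
        counts += np.histogram(t, bins=edges)[0]
    if short:
        warnings.warn(f"{short} trial(s) shorter than the {span:.2f} s ramp span")
    rate = counts / (len(ids) * bin_s)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, rate


def _sliding_slopes(
    centers: np.ndarray, rate: np.ndarray, window: float, bin_s: float
) -> tuple[np.ndarray, np.ndarray]:
    w_bins = int(round(window / bin_s))
    slopes, rs = [], []
    for i in range(0, rate.size - w_bins + 1):
        x = centers[i : i + w_bins]
        y = rate[i : i + w_bins]
        slope, _ = np.polyfit(x, y, 1)
        sy = np.std(y)
        r = 0.0 if sy == 0 else float(np.corrcoef(x, y)[0, 1])
        slopes.append(float(slope))
        rs.append(r)
    return np.asarray(slopes), np.asarray(rs)


def ramp_index(
    session: Session,
    unit: str,
    bin_s: float = 0.05,
    window: float = 0.5,
    start_before_response: float = 0.85,
    trial_ids: list[str] | None = None,
) -> float:
    """Maximum sliding-window regression slope of the response-aligned rate,
    in (spikes/s) per s."""
    ids = trial_ids if trial_ids is not None else [t.trial_id for t in session.trials]
    if len(ids) < 5:
        raise ValueError("ramp index needs at least 5 trials")
    centers, rate = _response_aligned_rate(session, unit, ids, bin_s, start_before_response)
    slopes, _ = _sliding_slopes(centers, rate, window, bin_s)
    return float(slopes.max())


def bootstrap_ramp_indices(
    session: Session,
    unit: str,
    n_boot: int = 1000,
    subsample: float = 0.9,
    seed: int | None = None,
    bin_s: float = 0.05,
    window: float = 0.5,
    start_before_response: float = 0.85,
) -> tuple[np.ndarray, float, float]:
    """Subsampled-bootstrap ramp indices plus the full-data best-window
    Pearson r and the mean rate over the ramp span (the baseline for the
    relative-change criterion)."""
    rng = np.random.default_rng(seed)
    ids = [t.trial_id for t in session.trials]
    m = max(5, int(np.floor(subsample * len(ids))))
    samples = []
    for _ in range(n_boot):
        sub = [ids[i] for i in rng.choice(len(ids), size=min(m, len(ids)), replace=False)]
        c, r = _response_aligned_rate(session, unit, sub, bin_s, start_before_response)
        slopes, _ = _sliding_slopes(c, r, window, bin_s)
        samples.append(float(slopes.max()))
    centers, rate = _response_aligned_rate(session, unit, ids, bin_s, start_before_response)
    slopes, rs = _sliding_slopes(centers, rate, window, bin_s)
    r_best = float(rs[np.argmax(slopes)])
    baseline = float(rate.mean())
    return np.asarray(samples), r_best, baseline


def classify_ramping(
    ramp_index_samples: np.ndarray,
    rate_baseline: float,
    threshold: float = 0.5,
    r_best: float = 1.0,
    r_threshold: float = 0.5,
    window: float = 0.5,
    alpha: float = 0.05,
) -> bool:
    """Ramping iff the slope implies an appreciable rate change.

    The predicted change over the regression window, |slope| * window,
    relative to the baseline rate must exceed ``threshold`` (50% by
    default) in at least 1-alpha of the bootstrap samples, and the best
    window's regression r must exceed ``r_threshold``.
    """
    samples = np.asarray(ramp_index_samples, dtype=float)
    if samples.size == 0:
        raise ValueError("no ramp-index samples")
    change = np.abs(samples) * window
    if rate_baseline > 0:
        rel = change / rate_baseline
        passed = np.mean(rel >= threshold)
    else:
        warnings.warn("zero baseline rate; classifying by absolute change")
        passed = np.mean(change >= threshold)
    return bool(passed >= 1.0 - alpha and r_best > r_threshold)


@dataclass
class ResponsivenessReport:
    unit_id: str
    tone_modulated: bool
    tone_coverage: dict
    ramp_index: float
    ramping: bool
    zscore: float | None
    classification: str


def classify_unit(
    session: Session,
    unit: str,
    n_boot: int = 5000,
    ramp_boot: int = 1000,
    seed: int | None = None,
) -> ResponsivenessReport:
    """Full responsiveness report for one unit.

    NCR overall means sensory NCR (no tone modulation) *and* choice NCR
    (no ramping); the classification string records which criteria fired.
    """
    rng = np.random.default_rng(seed)
    tone_mod, coverage = tone_modulation_test(
        session, unit, n_boot=n_boot, seed=int(rng.integers(2**31 - 1))
    )
    samples, r_best, baseline = bootstrap_ramp_indices(
        session, unit, n_boot=ramp_boot, seed=int(rng.integers(2**31 - 1))
    )
    ramping = classify_ramping(samples, baseline, r_best=r_best)
    ri = ramp_index(session, unit)
    z = evoked_zscore(session, unit)
    if tone_mod and ramping:
        cls = "classically responsive"
    elif ramping:  # not tone modulated
        cls = "sensory NCR"
    elif tone_mod:  # not ramping
        cls = "choice NCR"
    else:
        cls = "NCR"
    return ResponsivenessReport(unit, tone_mod, coverage, ri, ramping, z, cls)


def evoked_zscore(session: Session, unit: str) -> float | None:
    """z = mu/sigma of per-trial spike-count changes, 100 ms pre vs. 100 ms
    tone window; absent (None) when the change has zero variance."""
    if len(session.trials) < 2:
        raise ValueError("need at least 2 trials")
    changes = []
    for trial in session.trials:
        t = session.spike_train(unit, trial.trial_id).spike_times
        changes.append(_count(t, TONE_WINDOW) - _count(t, (-0.1, 0.0)))
    changes = np.asarray(changes, dtype=float)
    sd = float(np.std(changes, ddof=1))
    if sd == 0:
        return None
    return float(changes.mean() / sd)


def receptive_field(session: Session, unit: str) -> tuple[float, float]:
    """Best frequency and half-height tuning bandwidth (octaves).

    The evoked change per frequency is the 50 ms tone-window firing rate
    minus the 50 ms pre-onset rate; bandwidth is the tuning-curve width at
    the mean of the maximum and minimum evoked rates, interpolated
    linearly on a log2 frequency axis.  A flat curve spans the full range.
    """
    by_freq: dict[float, list[float]] = {}
    for trial in session.trials:
        if trial.frequency_khz is None:
            raise ValueError("receptive_field needs per-trial frequency labels")
        t = session.spike_train(unit, trial.trial_id).spike_times
        change = (_count(t, (0.0, 0.05)) - _count(t, (-0.05, 0.0))) / 0.05
        by_freq.setdefault(float(trial.frequency_khz), []).append(change)
    freqs = np.array(sorted(by_freq))
    y = np.array([np.mean(by_freq[f]) for f in freqs])
    x = np.log2(freqs)
    best = float(freqs[int(np.argmax(y))])
    half = 0.5 * (y.max() + y.min())
    if np.isclose(y.max(), y.min()):
        return best, float(x[-1] - x[0])
    above = y >= half
    # leftmost and rightmost half-height crossings, edges if already above
    left = x[0]
    for i in range(y.size):
        if above[i]:
            if i > 0:
                left = np.interp(half, [y[i - 1], y[i]], [x[i - 1], x[i]])
            break
    right = x[-1]
    for i in range(y.size - 1, -1, -1):
        if above[i]:
            if i < y.size - 1:
                right = np.interp(half, [y[i + 1], y[i]], [x[i + 1], x[i]])
            break
    return best, float(right - left)


@dataclass
class SelectivityReport:
    stimulus_selectivity_index: float
    choice_selectivity_index: float
    multiplexed: bool
    decoding_uniplexing_index: float
    penalized: bool = False


def _logit_fit(p: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, bool]:
    p = np.clip(p, 1e-6, 1 - 1e-6)
    model = sm.GLM(p, X, family=sm.families.Binomial())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit()
        if np.all(np.isfinite(res.params)) and np.max(np.abs(res.params)) < 50:
            return np.asarray(res.params), False
    except Exception:
        pass
    res = model.fit_regularized(alpha=1e-3, L1_wt=0.0)
    return np.asarray(res.params), True


def selectivity_indices(per_trial: pd.DataFrame) -> SelectivityReport:
    """Stimulus/choice selectivity from logistic-link regressions.

    ``per_trial`` needs columns ``stimulus_posterior`` (p(target)),
    ``choice_posterior`` (p(go)), ``stimulus`` and ``choice`` (true
    labels).  Each decoding probability is regressed on both true labels;
    the stimulus selectivity index is (stimulus coefficient - choice
    coefficient) of the stimulus-probability model, choice selectivity is
    the mirror image, and a cell is multiplexed when both are positive.
    The decoding-based uniplexing index is the difference between mean
    stimulus and mean choice decoding performance.
    """
    if len(per_trial) < 20:
        raise ValueError("need at least 20 trials")
    s = (per_trial["stimulus"] == "target").to_numpy(dtype=float)
    c = (per_trial["choice"] == "go").to_numpy(dtype=float)
    if len(set(s)) < 2 or len(set(c)) < 2:
        raise ValueError("both labels must vary")
    X = np.column_stack([np.ones_like(s), s, c])
    beta_s, pen_s = _logit_fit(per_trial["stimulus_posterior"].to_numpy(dtype=float), X)
    beta_c, pen_c = _logit_fit(per_trial["choice_posterior"].to_numpy(dtype=float), X)
    stim_sel = float(beta_s[1] - beta_s[2])
    choice_sel = float(beta_c[2] - beta_c[1])
    p_stim = per_trial["stimulus_posterior"].to_numpy(dtype=float)
    p_choice = per_trial["choice_posterior"].to_numpy(dtype=float)
    perf_stim = np.where(s == 1, p_stim, 1 - p_stim).mean()
    perf_choice = np.where(c == 1, p_choice, 1 - p_choice).mean()
    return SelectivityReport(
        stimulus_selectivity_index=stim_sel,
        choice_selectivity_index=choice_sel,
        multiplexed=bool(stim_sel > 0 and choice_sel > 0),
        decoding_uniplexing_index=float(perf_stim - perf_choice),
        penalized=pen_s or pen_c,
    )


def uniplexing_projection(
    stimulus_selectivity: np.ndarray, choice_selectivity: np.ndarray
) -> np.ndarray:
    """Signed orthogonal projection of each unit's (stimulus, choice)
    selectivity pair onto the across-cohort regression line.

    Near-zero values mark multiplexed cells; positive and negative values
    mark stimulus- and choice-uniplexed cells respectively.
    """
    x = np.asarray(stimulus_selectivity, dtype=float)
    y = np.asarray(choice_selectivity, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 units for the cohort regression")
    slope, intercept = np.polyfit(x, y, 1)
    d = np.array([1.0, slope]) / np.hypot(1.0, slope)
    if d[0] < 0:  # orient the axis so positive means stimulus-selective
        d = -d
    pts = np.column_stack([x, y - intercept])
    coords = pts @ d
    return coords - coords.mean()
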