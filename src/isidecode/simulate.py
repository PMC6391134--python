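"""Synthetic sessions with known ground truth.

Model cells are generated the way the method's illustrative examples are
built: each trial's spike train is produced by randomly sampling from the
appropriate conditional ISI distribution (here a mixture of log-normals),
and evoked responses are created *without* altering the ISI distribution
by circularly shifting the trial's spike pattern so that one spike during
stimulus presentation lands at approximately 30 ms (SD 10 ms).  Three
presets reproduce the canonical dissociations:

``fig2a``  evoked target response and distinct conditional ISI mixtures;
``fig2b``  evoked target response, identical ISI mixtures (rate codes,
           ISIs do not);
``fig2c``  no evoked response, distinct ISI mixtures (ISIs code, the
           trial-averaged rate does not — the non-classically responsive
           case).

The distinct-mixture presets match the mean ISI across conditions, so the
mean firing rate carries no information; ``fig2b`` uses one mixture for
both conditions, so the ISI distribution carries none.  Sessions also
carry a go/no-go label structure with configurable hit and false-alarm
rates (defaults mirror trained-animal behavior: 88% hits, 7% false
alarms), log-normal go-trial lengths around 1.5 s, and no-go trials
truncated at the mean correct-go response time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .session import Session, SpikeTrain, Trial

__all__ = [
    "CellSpec",
    "SessionSpec",
    "GroundTruth",
    "fig2a_cell",
    "fig2b_cell",
    "fig2c_cell",
    "homogeneous_cell",
    "ramping_cell",
    "mixture_mean_isi",
    "sample_mixture",
    "sample_trial",
    "inject_evoked_spike",
    "make_session",
    "make_consensus_ensemble",
    "preset_session",
    "PRESETS",
]

# log-normal mixture components as (weight, mean of log-ISI, sd of log-ISI)
Mixture = list[tuple[float, float, float]]

_SIGMA = 0.35
_DISTINCT_TARGET: Mixture = [
    (0.5, float(np.log(0.03)), _SIGMA),
    (0.5, float(np.log(0.24)), _SIGMA),
]
# unimodal mixture with the same mean ISI as the bimodal target mixture,
# so conditional mean rates match and the PSTH carries no information
_MATCHED_MEAN = 0.5 * (0.03 + 0.24) * float(np.exp(_SIGMA**2 / 2))
_DISTINCT_NONTARGET: Mixture = [
    (1.0, float(np.log(_MATCHED_MEAN)) - _SIGMA**2 / 2, _SIGMA)
]


def mixture_mean_isi(mixture: Mixture) -> float:
    """E[ISI] of a log-normal mixture: sum of w * exp(mu + sigma^2/2)."""
    return float(sum(w * np.exp(mu + s * s / 2) for w, mu, s in mixture))


@dataclass
class CellSpec:
    """Generative recipe for one model cell.

    ``isi_params`` maps condition labels (target/non-target, or go/no-go)
    to log-normal mixtures in log-ISI.  ``evoked`` adds the circular-shift
    evoked spike on target trials.  ``epoch`` restricts the conditional
    structure to a trial epoch: outside it, ``off_epoch_params`` applies.
    """

    cell_kind: str = "ncr_distinct_isi"
    isi_params: dict[str, Mixture] = field(
        default_factory=lambda: {
            "target": list(_DISTINCT_TARGET),
            "non-target": list(_DISTINCT_NONTARGET),
        }
    )
    evoked: bool = False
    evoked_time_mean: float = 0.030
    evoked_time_sd: float = 0.010
    ramp_slope: float = 0.0  # (spikes/s)/s, for the "ramping" kind
    base_rate: float = 8.0  # spikes/s, for "homogeneous"/"ramping" kinds
    epoch: tuple[float, float] | None = None
    off_epoch_params: dict[str, Mixture] | None = None

    def __post_init__(self):
        for cond, mix in self.isi_params.items():
            w = sum(m[0] for m in mix)
            if not np.isclose(w, 1.0):
                raise ValueError(f"mixture weights for {cond!r} sum to {w}, not 1")
            if any(m[2] < 0 for m in mix):
                raise ValueError("mixture sds must be >= 0")

    @property
    def variable(self) -> str:
        return "stimulus" if "target" in self.isi_params else "choice"


def fig2a_cell() -> CellSpec:
    """Evoked target response and distinct conditional ISI mixtures."""
    return CellSpec(cell_kind="evoked_distinct_isi", evoked=True)


def fig2b_cell() -> CellSpec:
    """Evoked target response, identical ISI mixtures for both conditions."""
    return CellSpec(
        cell_kind="evoked_identical_isi",
        isi_params={
            "target": list(_DISTINCT_NONTARGET),
            "non-target": list(_DISTINCT_NONTARGET),
        },
        evoked=True,
    )


def fig2c_cell() -> CellSpec:
    """No evoked response, distinct ISI mixtures (non-classically responsive)."""
    return CellSpec(cell_kind="ncr_distinct_isi", evoked=False)


def homogeneous_cell(rate: float = 8.0) -> CellSpec:
    """Stationary Poisson cell, condition-blind."""
    return CellSpec(
        cell_kind="homogeneous",
        isi_params={"target": [(1.0, float(np.log(1.0 / rate)), 0.0)],
                    "non-target": [(1.0, float(np.log(1.0 / rate)), 0.0)]},
        base_rate=rate,
    )


def ramping_cell(slope: float = 10.0, base_rate: float = 8.0) -> CellSpec:
    """Rate ramps linearly at ``slope`` (spikes/s)/s over the final second."""
    return CellSpec(cell_kind="ramping", ramp_slope=slope, base_rate=base_rate)


PRESETS = {"fig2a": fig2a_cell, "fig2b": fig2b_cell, "fig2c": fig2c_cell}


def sample_mixture(mixture: Mixture, size: int, rng: np.random.Generator) -> np.ndarray:
    """Direct i.i.d. draws from a log-normal mixture."""
    w = np.array([m[0] for m in mixture])
    comp = rng.choice(len(mixture), size=size, p=w / w.sum())
    mu = np.array([m[1] for m in mixture])[comp]
    sd = np.array([m[2] for m in mixture])[comp]
    return np.exp(mu + sd * rng.standard_normal(size))


def _draw_isi(cell: CellSpec, condition: str, t: float, rng: np.random.Generator) -> float:
    params = cell.isi_params
    if cell.epoch is not None and not (cell.epoch[0] <= t < cell.epoch[1]):
        params = cell.off_epoch_params or params
    mix = params[condition]
    return float(sample_mixture(mix, 1, rng)[0])


def _circular_segment(
    mixture: Mixture, seg_len: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary spike pattern on a circle of circumference ``seg_len``.

    ISIs are laid down from a uniformly random phase and wrapped; a
    circular rotation of the result is then exactly distribution-
    preserving, which is what makes the evoked-spike construction leave
    the ISI statistics untouched.
    """
    u = rng.uniform(0.0, seg_len)
    cum = [0.0]
    while cum[-1] < seg_len:
        cum.append(cum[-1] + float(sample_mixture(mixture, 1, rng)[0]))
    c = np.asarray(cum[:-1])
    return np.sort((u + c) % seg_len)


def sample_trial(
    cell: CellSpec,
    condition: str,
    length: float,
    rng: np.random.Generator,
    t_start: float = -0.3,
) -> np.ndarray:
    """Spike times of one trial, laid down by cumulative ISI draws.

    Spikes are generated from ``t_start`` (pre-onset baseline included) up
    to ``length``; the first spike is placed uniformly within one expected
    ISI of the start.  Homogeneous and ramping kinds instead draw from the
    corresponding (in)homogeneous Poisson process by thinning.  Evoked
    cells are generated circularly (pre-onset baseline as an independent
    stationary segment) so that the evoked rotation — and the circle cut —
    affect both conditions' ISI statistics identically.
    """
    if cell.cell_kind in ("homogeneous", "ramping"):
        return _sample_rate_cell(cell, length, rng, t_start)
    if cell.evoked and cell.epoch is None:
        mix = cell.isi_params[condition]
        parts = []
        if t_start < 0.0:
            parts.append(_circular_segment(mix, -t_start, rng) + t_start)
        parts.append(_circular_segment(mix, length, rng))
        return np.concatenate(parts)
    mean_isi = mixture_mean_isi(cell.isi_params[condition])
    t = t_start + rng.uniform(0.0, mean_isi)
    times = []
    while t < length:
        times.append(t)
        t += _draw_isi(cell, condition, max(t, 0.0), rng)
    return np.asarray(times)


def _sample_rate_cell(
    cell: CellSpec, length: float, rng: np.random.Generator, t_start: float
) -> np.ndarray:
    ramp_span = 1.0

    def rate(t: np.ndarray) -> np.ndarray:
        r = np.full_like(t, float(cell.base_rate))
        if cell.cell_kind == "ramping":
            r = r + cell.ramp_slope * np.maximum(0.0, t - (length - ramp_span))
        return np.maximum(r, 0.1)

    r_max = float(rate(np.linspace(t_start, length, 64)).max())
    n = rng.poisson(r_max * (length - t_start))
    cand = np.sort(rng.uniform(t_start, length, n))
    keep = rng.uniform(0, r_max, n) < rate(cand)
    return cand[keep]


def inject_evoked_spike(
    spike_times: np.ndarray,
    length: float,
    rng: np.random.Generator,
    mean: float = 0.030,
    sd: float = 0.010,
) -> tuple[np.ndarray, float | None]:
    """Circularly shift the in-trial spike pattern so one spike lands on a
    drawn evoked time ~ N(mean, sd).

    The rotation is modulo the trial length, so the within-trial ISI
    multiset is preserved except for the single wrap-around interval.
    Pre-onset spikes are left in place.  Returns the new spike times and
    the designated evoked-spike time (None when fewer than 2 in-trial
    spikes exist to rotate).
    """
    t = np.asarray(spike_times, dtype=float)
    pre = t[t < 0.0]
    s = t[(t >= 0.0) & (t < length)]
    if s.size < 2:
        return t, None
    e = float(np.clip(rng.normal(mean, sd), 0.0, length * 0.5))
    deltas = (e - s) % length
    circ = np.minimum(deltas, length - deltas)
    delta = float(deltas[int(np.argmin(circ))])
    shifted = np.sort((s + delta) % length)
    return np.concatenate([pre, shifted]), e


@dataclass
class SessionSpec:
    """Recipe for a full labeled synthetic session."""

    n_trials: int = 200
    p_target: float = 0.5
    hit_rate: float = 0.88
    false_alarm_rate: float = 0.07
    go_length_mean: float = 1.5
    go_length_sigma_log: float = 0.2
    length_bounds: tuple[float, float] = (0.5, 3.0)
    cells: list[CellSpec] = field(default_factory=lambda: [fig2c_cell()])
    pre_trial: float = 0.3
    seed: int | None = None

    def __post_init__(self):
        if self.n_trials < 4:
            raise ValueError("need at least 4 trials")
        for p in (self.p_target, self.hit_rate, self.false_alarm_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Every draw an oracle test needs to re-derive the session."""

    mixtures: list[dict[str, Mixture]]
    evoked_times: dict[tuple[str, str], float]  # (unit, trial) -> designated time
    isi_counts: dict[tuple[str, str], int]  # in-window ISI count per (unit, trial)
    labels: dict[str, tuple[str, str]]  # trial -> (stimulus, choice)


def make_session(spec: SessionSpec) -> tuple[Session, GroundTruth]:
    """Generate a labeled session and its ground truth.

    Stimulus is Bernoulli(p_target); choice follows the hit / false-alarm
    rates; outcomes follow the task rules.  Go trials end at their
    (sampled) response time; no-go trials end at the mean correct-go
    response time, mirroring the decoding-window convention.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_trials
    stims = np.where(rng.random(n) < spec.p_target, "target", "non-target")
    p_go = np.where(stims == "target", spec.hit_rate, spec.false_alarm_rate)
    choices = np.where(rng.random(n) < p_go, "go", "no-go")
    lo, hi = spec.length_bounds
    go_rt = np.clip(
        spec.go_length_mean * np.exp(spec.go_length_sigma_log * rng.standard_normal(n)),
        lo,
        hi,
    )
    # ensure at least one correct go trial so the no-go window is defined
    if not np.any((choices == "go") & (stims == "target")):
        stims[0], choices[0] = "target", "go"
    correct_go = (choices == "go") & (stims == "target")
    nogo_end = float(np.mean(go_rt[correct_go]))

    trials, labels = [], {}
    for i in range(n):
        tid = f"t{i:04d}"
        is_go = choices[i] == "go"
        trials.append(
            Trial(
                trial_id=tid,
                stimulus=str(stims[i]),
                choice=str(choices[i]),
                tone_onset=0.0,
                response_time=float(go_rt[i]) if is_go else None,
            )
        )
        labels[tid] = (str(stims[i]), str(choices[i]))

    spikes = []
    evoked_times: dict[tuple[str, str], float] = {}
    isi_counts: dict[tuple[str, str], int] = {}
    for ci, cell in enumerate(spec.cells):
        unit = f"u{ci}"
        for i, trial in enumerate(trials):
            end = trial.response_time if trial.choice == "go" else nogo_end
            cond = trial.stimulus if cell.variable == "stimulus" else trial.choice
            t = sample_trial(cell, cond, end, rng, t_start=-spec.pre_trial)
            if cell.evoked and trial.stimulus == "target":
                t, e = inject_evoked_spike(
                    t, end, rng, cell.evoked_time_mean, cell.evoked_time_sd
                )
                if e is not None:
                    evoked_times[(unit, trial.trial_id)] = e
            # in-window ISI count under the final-spike rule
            finals = t[1:]
            isi_counts[(unit, trial.trial_id)] = int(
                np.count_nonzero((finals >= 0.0) & (finals < end))
            )
            spikes.append(SpikeTrain(unit, trial.trial_id, t))

    session = Session(trials, spikes, {"generator": "isidecode.simulate"}, spec.pre_trial)
    session.assign_windows()
    truth = GroundTruth(
        mixtures=[dict(c.isi_params) for c in spec.cells],
        evoked_times=evoked_times,
        isi_counts=isi_counts,
        labels=labels,
    )
    return session, truth


def preset_session(
    preset: str, n_trials: int = 200, seed: int | None = None,
    trial_length: float = 1.5,
) -> tuple[Session, GroundTruth]:
    """Model-cell session for one of the presets, with fixed-length trials.

    The model-cell experiments isolate spike-statistics coding (ISI vs.
    rate), so every trial lasts exactly ``trial_length`` seconds:
    variable response times would let either decoder read the stimulus
    out of the trial duration instead of the spike train.
    """
    spec = SessionSpec(
        n_trials=n_trials,
        cells=[PRESETS[preset]()],
        seed=seed,
        go_length_mean=trial_length,
        go_length_sigma_log=0.0,
        length_bounds=(trial_length, trial_length),
    )
    return make_session(spec)


def _random_mixture(rng: np.random.Generator, n_comp: int = 2) -> Mixture:
    w = rng.dirichlet(np.ones(n_comp))
    mu = np.log(rng.uniform(0.02, 0.5, n_comp))
    sd = rng.uniform(0.25, 0.5, n_comp)
    return [(float(wi), float(mi), float(si)) for wi, mi, si in zip(w, mu, sd)]


def make_consensus_ensemble(
    relation: str,
    n_members: int,
    base_cell: CellSpec | None = None,
    spec: SessionSpec | None = None,
) -> tuple[Session, GroundTruth]:
    """Session whose units have a prescribed LLR relationship.

    ``identical`` clones the base cell; ``sign_flipped`` swaps the
    condition mixtures on alternate members; ``independent`` draws fresh
    random mixtures per member; ``epoch_localized`` shares the base
    conditional structure only inside a trial epoch (members disagree
    elsewhere).
    """
    base = base_cell or fig2c_cell()
    spec = spec or SessionSpec()
    rng = np.random.default_rng(spec.seed)
    conds = list(base.isi_params)
    cells: list[CellSpec] = []
    for m in range(n_members):
        if relation == "identical":
            cells.append(replace(base))
        elif relation == "sign_flipped":
            if m % 2 == 0:
                cells.append(replace(base))
            else:
                swapped = {conds[0]: base.isi_params[conds[1]],
                           conds[1]: base.isi_params[conds[0]]}
                cells.append(replace(base, isi_params=swapped))
        elif relation == "independent":
            cells.append(
                replace(
                    base,
                    isi_params={c: _random_mixture(rng) for c in conds},
                    evoked=False,
                )
            )
        elif relation == "epoch_localized":
            cells.append(
                replace(
                    base,
                    epoch=(0.5, 1.5),
                    off_epoch_params={c: _random_mixture(rng) for c in conds},
                )
            )
        else:
            raise ValueError(f"unknown relation {relation!r}")
    spec = replace(spec, cells=cells, seed=int(rng.integers(2**31 - 1)))
    return make_session(spec)
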