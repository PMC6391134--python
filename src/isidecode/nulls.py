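"""Shuffling controls for decoding significance.

Two nulls are provided.  The first builds synthetic spike trains per trial
by resampling, with replacement, from the pooled set of all observed ISIs
irrespective of task condition — spike-timing statistics survive but any
relationship to the labels is destroyed.  The second leaves the spike data
intact and permutes the (stimulus, choice) label pairs across trials.
Either way, a decoder run on the null session should perform at chance
(50%), and repeating the randomization yields the null performance
distribution for a permutation-style test.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .decoder import cross_validated_decode, ISIDecoderBackend
from .session import Session, SpikeTrain, expected_outcome, extract_isis

__all__ = ["NullSpec", "synthetic_session", "permute_conditions", "null_distribution"]


@dataclass
class NullSpec:
    """Which shuffle to run and how many repetitions."""

    kind: str = "isi_resample"  # or "condition_permute"
    reps: int = 1240
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in ("isi_resample", "condition_permute"):
            raise ValueError(f"unknown null kind {self.kind!r}")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


def synthetic_session(
    session: Session,
    unit: str,
    seed: int | None = None,
    anchor: str = "first_spike",
) -> Session:
    """Replace one unit's spikes with condition-agnostic ISI-resampled trains.

    Per trial, ISIs are drawn with replacement from the unit's pooled
    in-window library and laid down from the trial's first observed spike
    time (``anchor="first_spike"``, default) or from 0 (``anchor="zero"``)
    until the trial's effective end is exceeded.  Trial lengths and labels
    are preserved exactly.
    """
    rng = np.random.default_rng(seed)
    session.assign_windows()
    pooled = []
    for trial in session.trials:
        obs = extract_isis(session.spike_train(unit, trial.trial_id), (0.0, trial.effective_end))
        pooled.extend(o.isi for o in obs)
    if not pooled:
        raise ValueError(f"unit {unit!r} has no in-window ISIs to resample")
    pooled = np.asarray(pooled, dtype=float)

    new_spikes = []
    for st in session.spikes:
        if st.unit_id != unit:
            new_spikes.append(st)
            continue
        trial = session.trial(st.trial_id)
        end = trial.effective_end
        if anchor == "first_spike":
            in_window = st.spike_times[(st.spike_times >= 0.0) & (st.spike_times < end)]
            if in_window.size == 0:
                new_spikes.append(SpikeTrain(unit, st.trial_id, np.empty(0)))
                continue
            t = float(in_window[0])
        elif anchor == "zero":
            t = 0.0
        else:
            raise ValueError(f"unknown anchor {anchor!r}")
        times = [t]
        while times[-1] <= end:
            times.append(times[-1] + float(pooled[rng.integers(pooled.size)]))
        times = np.array(times[:-1])  # drop the draw that exceeded the trial end
        times = times[times < end]
        new_spikes.append(SpikeTrain(unit, st.trial_id, times))
    out = Session(
        copy.deepcopy(session.trials), new_spikes, dict(session.metadata), session.pre_trial_bound
    )
    return out


def permute_conditions(
    session: Session, seed: int | None = None, joint: bool = True
) -> Session:
    """Permute the task labels across trials, leaving all spikes intact.

    By default the (stimulus, choice) pairs are permuted jointly, which
    preserves their correlation structure; ``joint=False`` permutes the
    two labels independently.  Outcomes are recomputed from the task
    rules; response times and decoding windows stay with their original
    trials so the spike data and windowing are untouched.
    """
    rng = np.random.default_rng(seed)
    session.assign_windows()
    n = len(session.trials)
    if n < 2:
        raise ValueError("need at least 2 trials to permute")
    stims = [t.stimulus for t in session.trials]
    choices = [t.choice for t in session.trials]
    if joint:
        perm = rng.permutation(n)
        stims = [stims[i] for i in perm]
        choices = [choices[i] for i in perm]
    else:
        ps, pc = rng.permutation(n), rng.permutation(n)
        stims = [stims[i] for i in ps]
        choices = [choices[i] for i in pc]
    new_trials = []
    for trial, s, c in zip(session.trials, stims, choices):
        t = copy.deepcopy(trial)
        t.stimulus = s
        t.choice = c
        t.outcome = expected_outcome(s, c)
        new_trials.append(t)
    return Session(new_trials, session.spikes, dict(session.metadata), session.pre_trial_bound)


def null_distribution(
    session: Session,
    units: str | list[str],
    variable: str,
    spec: NullSpec,
    folds: int = 10,
    backend=None,
    decode_reps: int = 1,
) -> np.ndarray:
    """Null decoding-performance distribution, one value per repetition.

    Each repetition independently regenerates a null session and pushes it
    through the identical cross-validated decoding pipeline.
    """
    if isinstance(units, str):
        units = [units]
    backend = backend or ISIDecoderBackend()
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.reps):
        sub = int(rng.integers(2**31 - 1))
        if spec.kind == "isi_resample":
            null_sess = session
            for u in units:
                null_sess = synthetic_session(null_sess, u, seed=sub)
        else:
            null_sess = permute_conditions(session, seed=sub)
        summary, _ = cross_validated_decode(
            null_sess, units, variable, backend, folds=folds, reps=decode_reps, seed=sub
        )
        out.append(summary.mean_performance)
    return np.asarray(out)
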