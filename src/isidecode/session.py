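"""Trial-aligned spike data model: sessions, windowing, ISI extraction, unit filters.

Time base is trial-aligned seconds with 0 = tone onset.  All window
arithmetic is half-open ``[start, end)``.  Spikes recorded before onset are
retained down to a configurable pre-trial bound (default 0.3 s) because the
responsiveness statistics need pre-stimulus baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeTrain",
    "Trial",
    "Session",
    "ISIObservation",
    "ValidationError",
    "STIMULI",
    "CHOICES",
    "expected_outcome",
    "trial_window",
    "extract_isis",
    "filter_units",
    "sliding_windows",
]

STIMULI = ("target", "non-target")
CHOICES = ("go", "no-go")
OUTCOMES = ("correct", "error")

#: default retention bound for pre-onset spikes, seconds before tone onset
DEFAULT_PRE_TRIAL_BOUND = 0.3


class ValidationError(ValueError):
    """Raised when session data violate the task's structural rules."""


def expected_outcome(stimulus: str, choice: str) -> str:
    """Outcome implied by the go/no-go task rules.

    Target + go and non-target + no-go are correct; the other two
    combinations (miss, false alarm) are errors.
    """
    if stimulus == "target":
        return "correct" if choice == "go" else "error"
    return "error" if choice == "go" else "correct"


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times of one unit on one trial, trial-aligned seconds."""

    unit_id: str
    trial_id: str
    spike_times: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", times)
        if times.size and not np.all(np.diff(times) > 0):
            raise ValidationError(
                f"spike times not strictly increasing for unit {self.unit_id!r} "
                f"trial {self.trial_id!r}"
            )
        if times.size and not np.all(np.isfinite(times)):
            raise ValidationError(
                f"non-finite spike time for unit {self.unit_id!r} trial {self.trial_id!r}"
            )


@dataclass
class Trial:
    """One behavioral trial of the go/no-go task.

    ``tone_onset`` is in session clock units and defines time 0 of the
    trial-aligned frame; spike times stored in :class:`SpikeTrain` are
    already aligned.  ``response_time`` is absent (None) on no-go trials.
    ``effective_end`` is the end of the decoding window and is filled in by
    :func:`trial_window`.
    """

    trial_id: str
    stimulus: str
    choice: str
    tone_onset: float = 0.0
    response_time: float | None = None
    outcome: str | None = None
    effective_end: float | None = None
    frequency_khz: float | None = None

    def __post_init__(self):
        self.stimulus = _normalize(self.stimulus, STIMULI, "stimulus")
        self.choice = _normalize(self.choice, CHOICES, "choice")
        if self.outcome is None:
            self.outcome = expected_outcome(self.stimulus, self.choice)
        else:
            self.outcome = _normalize(self.outcome, OUTCOMES, "outcome")
            expected = expected_outcome(self.stimulus, self.choice)
            if self.outcome != expected:
                raise ValidationError(
                    f"trial {self.trial_id!r}: outcome {self.outcome!r} inconsistent "
                    f"with ({self.stimulus}, {self.choice}) -> {expected!r}"
                )
        if self.effective_end is not None and not self.effective_end > 0:
            raise ValidationError(f"trial {self.trial_id!r}: effective_end must be > 0")

    @property
    def category(self) -> tuple[str, str]:
        return (self.stimulus, self.choice)


def _normalize(value: str, allowed: tuple[str, ...], name: str) -> str:
    v = str(value).strip().lower().replace("_", "-")
    aliases = {"nontarget": "non-target", "nogo": "no-go"}
    v = aliases.get(v, v)
    if v not in allowed:
        raise ValidationError(f"invalid {name} value {value!r}; expected one of {allowed}")
    return v


@dataclass
class Session:
    """All trials and spike trains of one recording session."""

    trials: list[Trial]
    spikes: list[SpikeTrain]
    metadata: dict = field(default_factory=dict)
    pre_trial_bound: float = DEFAULT_PRE_TRIAL_BOUND

    def __post_init__(self):
        self._trial_index = {t.trial_id: t for t in self.trials}
        if len(self._trial_index) != len(self.trials):
            raise ValidationError("duplicate trial_id in session")
        self._spike_index: dict[tuple[str, str], SpikeTrain] = {}
        for st in self.spikes:
            if st.trial_id not in self._trial_index:
                raise ValidationError(
                    f"spike train references unknown trial {st.trial_id!r}"
                )
            key = (st.unit_id, st.trial_id)
            if key in self._spike_index:
                raise ValidationError(f"duplicate spike train for {key}")
            if st.spike_times.size and st.spike_times[0] < -self.pre_trial_bound:
                raise ValidationError(
                    f"spike at {st.spike_times[0]:.4f} s precedes the pre-trial bound "
                    f"{-self.pre_trial_bound:.4f} s (unit {st.unit_id!r}, trial {st.trial_id!r})"
                )
            self._spike_index[key] = st

    @property
    def units(self) -> list[str]:
        seen: dict[str, None] = {}
        for st in self.spikes:
            seen.setdefault(st.unit_id, None)
        return list(seen)

    def trial(self, trial_id: str) -> Trial:
        return self._trial_index[trial_id]

    def spike_train(self, unit_id: str, trial_id: str) -> SpikeTrain:
        key = (unit_id, trial_id)
        if key not in self._spike_index:
            return SpikeTrain(unit_id, trial_id, np.empty(0))
        return self._spike_index[key]

    def category_counts(self) -> dict[tuple[str, str], int]:
        """Trial counts in each of the four (stimulus, choice) categories."""
        counts = {(s, c): 0 for s in STIMULI for c in CHOICES}
        for t in self.trials:
            counts[t.category] += 1
        return counts

    def with_trials(self, trials: list[Trial]) -> "Session":
        keep = {t.trial_id for t in trials}
        spikes = [s for s in self.spikes if s.trial_id in keep]
        return Session(trials, spikes, dict(self.metadata), self.pre_trial_bound)

    def assign_windows(self, reference: str = "correct-go") -> "Session":
        """Fill in any missing ``effective_end`` (see :func:`trial_window`).

        Already-assigned windows are left untouched, so label-permuted
        sessions keep the windows of the original trials.
        """
        for t in self.trials:
            if t.effective_end is None:
                trial_window(t, self, reference=reference)
        return self


@dataclass(frozen=True)
class ISIObservation:
    """A single interspike interval and the time of its closing spike.

    ``final_spike_time`` anchors the observation to a sliding window: the
    ISI is assessed with the density whose window center is closest to it.
    """

    isi: float
    final_spike_time: float

    def __post_init__(self):
        if not self.isi > 0:
            raise ValidationError(f"ISI must be > 0, got {self.isi}")


def trial_window(
    trial: Trial, session: Session, reference: str = "correct-go"
) -> tuple[float, float]:
    """Decoding window of a trial: stimulus onset to the behavioral response.

    Go trials end at their own response time.  No-go trials have no
    response, so they end at the mean response time of a reference set of
    go trials: ``"correct-go"`` (default) uses correct go trials only,
    ``"all-go"`` uses every go trial.  The result is cached on
    ``trial.effective_end``.
    """
    if trial.choice == "go":
        if trial.response_time is None:
            raise ValidationError(f"go trial {trial.trial_id!r} lacks a response time")
        end = float(trial.response_time)
    else:
        if reference == "correct-go":
            ref = [
                t.response_time
                for t in session.trials
                if t.choice == "go" and t.outcome == "correct"
            ]
        elif reference == "all-go":
            ref = [t.response_time for t in session.trials if t.choice == "go"]
        else:
            raise ValueError(f"unknown reference set {reference!r}")
        ref = [r for r in ref if r is not None]
        if not ref:
            raise ValidationError(
                "no-go trial present but the session has no reference go trials; "
                "provide an explicit fallback trial end"
            )
        end = float(np.mean(ref))
    if not end > 0:
        raise ValidationError(f"trial {trial.trial_id!r}: window end {end} not positive")
    trial.effective_end = end
    return (0.0, end)


def extract_isis(
    spike_train: SpikeTrain, window: tuple[float, float]
) -> list[ISIObservation]:
    """ISIs of consecutive spike pairs whose *final* spike lies in the window.

    The first spike of a pair may precede the window (first-spike rule);
    inclusion is decided by the closing spike alone, on ``[start, end)``.
    Trains with fewer than two spikes yield no observations.
    """
    start, end = window
    t = spike_train.spike_times
    if t.size < 2:
        return []
    isis = np.diff(t)
    finals = t[1:]
    keep = (finals >= start) & (finals < end)
    return [ISIObservation(float(d), float(f)) for d, f in zip(isis[keep], finals[keep])]


def filter_units(
    session: Session,
    min_spikes: int = 3,
    min_trial_fraction: float = 0.8,
) -> list[str]:
    """Units with strictly more than ``min_spikes`` in-window spikes on at
    least ``min_trial_fraction`` of trials.

    Mirrors the recording-inclusion rule (>3 spikes per trial for 80% of
    trials) that guarantees enough ISIs to estimate the densities.
    """
    kept = []
    for unit in session.units:
        n_pass = 0
        for trial in session.trials:
            if trial.effective_end is None:
                trial_window(trial, session)
            t = session.spike_train(unit, trial.trial_id).spike_times
            n_in = int(np.count_nonzero((t >= 0.0) & (t < trial.effective_end)))
            if n_in > min_spikes:
                n_pass += 1
        if session.trials and n_pass >= min_trial_fraction * len(session.trials):
            kept.append(unit)
    return kept


def sliding_windows(
    end: float, length: float = 1.0, step: float = 0.1
) -> list[tuple[float, float, float]]:
    """Sliding-window layout ``(w_start, w_end, w_center)`` covering a trial.

    Windows of ``length`` seconds start at 0 and advance by ``step`` while
    ``w_start + length < end + step`` (strictly); a trial shorter than one
    window yields the single window ``(0, end)``.
    """
    if length <= 0 or step <= 0:
        raise ValueError("window length and step must be positive")
    if not end > 0:
        raise ValueError("trial end must be positive")
    if end <= length:
        return [(0.0, float(end), float(end) / 2.0)]
    # strict stopping rule; 1e-9 guards float accumulation at the boundary
    n = int(np.floor((end - length) / step + 1.0 - 1e-9)) + 1
    out = []
    for k in range(n):
        s = k * step
        out.append((s, s + length, s + length / 2.0))
    return out
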