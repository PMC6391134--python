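"""Tabular session I/O.

A session directory holds two CSV files (UTF-8, header row, "." decimals):

``spikes.csv``
    columns ``unit_id,trial_id,spike_time_s`` — trial-aligned float seconds.
``trials.csv``
    columns ``trial_id,stimulus,choice,tone_onset_s,response_time_s,outcome``
    (``response_time_s`` empty on no-go trials); an optional
    ``frequency_khz`` column carries tone frequency for receptive-field
    analyses.

An optional ``session.json`` provides free-form metadata.  Stimulus,
choice and outcome labels are normalized case-insensitively ("GO" -> "go").
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .session import Session, SpikeTrain, Trial, ValidationError

__all__ = ["read_session", "write_session", "FormatError"]

TRIAL_COLUMNS = ["trial_id", "stimulus", "choice", "tone_onset_s", "response_time_s", "outcome"]
SPIKE_COLUMNS = ["unit_id", "trial_id", "spike_time_s"]


class FormatError(ValueError):
    """Raised when a session file does not conform to the CSV dialect."""


def _require_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_session(
    path: str | Path,
    pre_trial_bound: float = 0.3,
    **format_options,
) -> Session:
    """Read and validate a session directory.

    Rejects duplicate ``(unit, trial, spike_time)`` rows and non-monotone
    spike times; spikes earlier than ``pre_trial_bound`` seconds before
    tone onset fail validation.
    """
    path = Path(path)
    trials_path = path / "trials.csv"
    spikes_path = path / "spikes.csv"
    for p in (trials_path, spikes_path):
        if not p.exists():
            raise FormatError(f"missing session file {p}")

    format_options.setdefault("float_precision", "round_trip")
    tdf = pd.read_csv(trials_path, dtype={"trial_id": str}, **format_options)
    _require_columns(tdf, TRIAL_COLUMNS, trials_path)
    trials = []
    for row in tdf.itertuples(index=False):
        rt = getattr(row, "response_time_s")
        rt = None if pd.isna(rt) else float(rt)
        outcome = getattr(row, "outcome")
        outcome = None if pd.isna(outcome) else str(outcome)
        freq = getattr(row, "frequency_khz", None)
        freq = None if freq is None or pd.isna(freq) else float(freq)
        trials.append(
            Trial(
                trial_id=str(row.trial_id),
                stimulus=str(row.stimulus),
                choice=str(row.choice),
                tone_onset=float(row.tone_onset_s),
                response_time=rt,
                outcome=outcome,
                frequency_khz=freq,
            )
        )

    sdf = pd.read_csv(spikes_path, dtype={"unit_id": str, "trial_id": str}, **format_options)
    _require_columns(sdf, SPIKE_COLUMNS, spikes_path)
    if sdf.duplicated(subset=SPIKE_COLUMNS).any():
        raise ValidationError(f"{spikes_path}: duplicate (unit, trial, spike_time) rows")
    spikes = []
    for (unit, trial), grp in sdf.groupby(["unit_id", "trial_id"], sort=True):
        times = grp["spike_time_s"].to_numpy(dtype=float)
        if not np.all(np.diff(times) >= 0):
            # rows are expected in time order within a train
            raise ValidationError(
                f"{spikes_path}: non-monotone spike times for unit {unit!r} trial {trial!r}"
            )
        spikes.append(SpikeTrain(str(unit), str(trial), times))

    metadata = {}
    meta_path = path / "session.json"
    if meta_path.exists():
        metadata = json.loads(meta_path.read_text())

    return Session(trials, spikes, metadata, pre_trial_bound=pre_trial_bound)


def write_session(session: Session, path: str | Path) -> None:
    """Write a session directory in canonical row order (round-trips with
    :func:`read_session`)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    trows = []
    for t in session.trials:
        trows.append(
            {
                "trial_id": t.trial_id,
                "stimulus": t.stimulus,
                "choice": t.choice,
                "tone_onset_s": t.tone_onset,
                "response_time_s": t.response_time,
                "outcome": t.outcome,
                **({"frequency_khz": t.frequency_khz} if t.frequency_khz is not None else {}),
            }
        )
    pd.DataFrame(trows).to_csv(path / "trials.csv", index=False)

    srows = []
    for st in sorted(session.spikes, key=lambda s: (s.unit_id, s.trial_id)):
        for time in st.spike_times:
            srows.append(
                {"unit_id": st.unit_id, "trial_id": st.trial_id, "spike_time_s": time}
            )
    pd.DataFrame(srows, columns=SPIKE_COLUMNS).to_csv(path / "spikes.csv", index=False)

    if session.metadata:
        (path / "session.json").write_text(json.dumps(session.metadata, indent=2))
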