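"""Sequential Bayesian single-trial decoding of stimulus and choice.

Each trial starts from agnostic beliefs, p(target) = p(non-target) = 50%
(and likewise for go / no-go).  As ISIs are observed in order of their
final spike, Bayes' rule updates the belief with the window-assigned
conditional ISI likelihood:

    p(target | ISI, t) = p(ISI | target, t) p(target, t)
        / [p(ISI | target, t) p(target, t) + p(ISI | non-target, t) p(non-target, t)]

Because ISIs are treated as independent, the final posterior equals the
normalized product of per-ISI likelihoods times the uniform prior, so the
update order cannot change the end-of-trial readout.  Performance of a
unit is estimated by repeated stratified 10-fold cross-validation: the
"decoding performance" is the mean posterior mass on the true
condition at trial end (certainty-weighted); thresholded accuracy is
reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .density import ConditionalISILikelihood, ISILibrary, EstimationError
from .session import Session, SpikeTrain, extract_isis, sliding_windows

__all__ = [
    "VARIABLE_CONDITIONS",
    "PosteriorTrace",
    "DecodingResult",
    "PerformanceSummary",
    "ISIDecoderBackend",
    "decode_trial",
    "decode_unit",
    "decode_ensemble",
    "cross_validated_decode",
    "predict_errors",
    "compare_to_null",
    "demanded_choice",
]

VARIABLE_CONDITIONS = {
    "stimulus": ("target", "non-target"),
    "choice": ("go", "no-go"),
}


def demanded_choice(stimulus: str) -> str:
    """The choice the task rules require for a stimulus."""
    return "go" if stimulus == "target" else "no-go"


@dataclass
class PosteriorTrace:
    """Within-trial belief trajectory for the first-listed condition."""

    variable: str
    update_times: np.ndarray
    posteriors: np.ndarray
    prior: float = 0.5


@dataclass
class DecodingResult:
    """End-of-trial readout for one decoded trial."""

    trial_id: str
    variable: str
    final_posterior_true: float
    predicted: str | None
    true_label: str


@dataclass
class PerformanceSummary:
    """Cross-validated decoding performance of a unit or ensemble.

    ``mean_performance`` is the certainty-weighted metric (mean posterior
    on the true condition); ``accuracy`` thresholds the posterior at 0.5
    with exact ties scored 0.5.  Chance is 0.5 for both.
    """

    variable: str
    mean_performance: float
    accuracy: float
    performance_reps: np.ndarray
    accuracy_reps: np.ndarray
    n_trials: int
    n_reps: int
    folds: int
    units: tuple[str, ...] = ()

    @property
    def sem(self) -> float:
        if self.performance_reps.size < 2:
            return float("nan")
        return float(np.std(self.performance_reps, ddof=1) / np.sqrt(self.performance_reps.size))


def _sigmoid(x: np.ndarray | float):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def decode_trial(
    likelihoods: tuple[ConditionalISILikelihood, ConditionalISILikelihood],
    spike_train: SpikeTrain,
    window: tuple[float, float],
    variable: str = "stimulus",
    true_label: str | None = None,
    trial_id: str | None = None,
) -> tuple[PosteriorTrace, DecodingResult]:
    """Decode a single trial with a fitted likelihood pair.

    ISIs are consumed in order of their final spike; a trial with no
    in-window ISI keeps the 50% prior.
    """
    model_a, model_b = likelihoods
    first, second = VARIABLE_CONDITIONS[variable]
    obs = extract_isis(spike_train, window)
    if obs:
        isis = np.array([o.isi for o in obs])
        finals = np.array([o.final_spike_time for o in obs])
        order = np.argsort(finals, kind="stable")
        isis, finals = isis[order], finals[order]
        la = model_a.evaluate_many(isis, finals)
        lb = model_b.evaluate_many(isis, finals)
        log_odds = np.cumsum(np.log(la) - np.log(lb))
        posteriors = _sigmoid(log_odds)
        times = finals
    else:
        posteriors = np.empty(0)
        times = np.empty(0)
    trace = PosteriorTrace(variable, times, posteriors)
    p_first = float(posteriors[-1]) if posteriors.size else 0.5
    if p_first > 0.5:
        predicted = first
    elif p_first < 0.5:
        predicted = second
    else:
        predicted = None  # exact tie: abstain
    p_true = None
    if true_label is not None:
        p_true = p_first if true_label == first else 1.0 - p_first
    result = DecodingResult(
        trial_id=trial_id or spike_train.trial_id,
        variable=variable,
        final_posterior_true=p_true if p_true is not None else p_first,
        predicted=predicted,
        true_label=true_label if true_label is not None else "",
    )
    return trace, result


class ISIDecoderBackend:
    """Fits conditional ISI likelihoods and produces per-ISI belief updates.

    The cross-validation engine is agnostic to the decoding model: a
    backend fits per-condition models on training trials and returns
    ``(update_times, log_likelihood_ratio_increments)`` for a test trial.
    """

    def __init__(
        self,
        window_length: float = 1.0,
        window_step: float = 0.1,
        cv_folds: int = 10,
        bandwidth_grid: np.ndarray | None = None,
        support: tuple[float, float] = (1e-3, 10.0),
    ):
        self.window_length = window_length
        self.window_step = window_step
        self.cv_folds = cv_folds
        self.bandwidth_grid = bandwidth_grid
        self.support = support

    def fit(
        self,
        session: Session,
        unit: str,
        training_ids: list[str],
        variable: str,
        rng: np.random.Generator,
    ) -> tuple[ConditionalISILikelihood, ConditionalISILikelihood]:
        first, second = VARIABLE_CONDITIONS[variable]
        ends = [session.trial(t).effective_end for t in training_ids]
        layout = sliding_windows(max(ends), self.window_length, self.window_step)
        models = []
        for cond in (first, second):
            obs = []
            for tid in training_ids:
                trial = session.trial(tid)
                label = trial.stimulus if variable == "stimulus" else trial.choice
                if label != cond:
                    continue
                obs.extend(
                    extract_isis(session.spike_train(unit, tid), (0.0, trial.effective_end))
                )
            if len(obs) < 2:
                raise EstimationError(
                    f"unit {unit!r}: condition {cond!r} has fewer than 2 training ISIs"
                )
            lib = ISILibrary(cond, obs)
            models.append(
                ConditionalISILikelihood.fit(
                    lib,
                    layout,
                    cv_folds=self.cv_folds,
                    bandwidth_grid=self.bandwidth_grid,
                    support=self.support,
                    rng=rng,
                )
            )
        return models[0], models[1]

    def trial_updates(
        self,
        models: tuple[ConditionalISILikelihood, ConditionalISILikelihood],
        session: Session,
        unit: str,
        trial_id: str,
    ) -> tuple[np.ndarray, np.ndarray]:
        trial = session.trial(trial_id)
        obs = extract_isis(
            session.spike_train(unit, trial_id), (0.0, trial.effective_end)
        )
        if not obs:
            return np.empty(0), np.empty(0)
        isis = np.array([o.isi for o in obs])
        finals = np.array([o.final_spike_time for o in obs])
        la = models[0].evaluate_many(isis, finals)
        lb = models[1].evaluate_many(isis, finals)
        return finals, np.log(la) - np.log(lb)


def _stratified_folds(
    session: Session, trial_ids: list[str], folds: int, rng: np.random.Generator
) -> dict[str, int]:
    """Deal trials of each (stimulus, choice) category round-robin into folds."""
    by_cat: dict[tuple[str, str], list[str]] = {}
    for tid in trial_ids:
        by_cat.setdefault(session.trial(tid).category, []).append(tid)
    assignment: dict[str, int] = {}
    offset = 0
    for cat in sorted(by_cat):
        ids = list(by_cat[cat])
        rng.shuffle(ids)
        for i, tid in enumerate(ids):
            assignment[tid] = (i + offset) % folds
        offset += len(ids)  # stagger so small categories spread over folds
    return assignment


def _effective_folds(session: Session, trial_ids: list[str], folds: int) -> int:
    counts = {}
    for tid in trial_ids:
        cat = session.trial(tid).category
        counts[cat] = counts.get(cat, 0) + 1
    smallest = min(counts.values())
    if smallest < folds:
        eff = max(2, smallest)
        warnings.warn(
            f"smallest trial category has {smallest} trials; reducing folds "
            f"{folds} -> {eff}",
            stacklevel=3,
        )
        return eff
    return folds


def cross_validated_decode(
    session: Session,
    units: list[str],
    variable: str,
    backend,
    folds: int = 10,
    reps: int = 124,
    seed: int | None = None,
) -> tuple[PerformanceSummary, pd.DataFrame]:
    """Repeated stratified k-fold decoding of one unit or ensemble.

    For an ensemble, per-unit likelihoods are fitted independently but a
    single shared posterior is updated by every unit's ISIs in
    chronological order of final-spike time.  Returns the performance
    summary plus a per-trial table of rep-averaged posteriors.
    """
    first, _ = VARIABLE_CONDITIONS[variable]
    session.assign_windows()
    trial_ids = [t.trial_id for t in session.trials]
    folds_eff = _effective_folds(session, trial_ids, folds)
    rng = np.random.default_rng(seed)

    perf_reps, acc_reps = [], []
    post_sum = {tid: 0.0 for tid in trial_ids}
    for _ in range(reps):
        fold_of = _stratified_folds(session, trial_ids, folds_eff, rng)
        p_true = {}
        for f in range(folds_eff):
            train_ids = [t for t in trial_ids if fold_of[t] != f]
            test_ids = [t for t in trial_ids if fold_of[t] == f]
            if not test_ids:
                continue
            models = {u: backend.fit(session, u, train_ids, variable, rng) for u in units}
            for tid in test_ids:
                times, deltas = [], []
                for u in units:
                    t_u, d_u = backend.trial_updates(models[u], session, u, tid)
                    times.append(t_u)
                    deltas.append(d_u)
                times = np.concatenate(times) if times else np.empty(0)
                deltas = np.concatenate(deltas) if deltas else np.empty(0)
                total = float(deltas.sum())
                p_first = float(_sigmoid(total)) if times.size else 0.5
                trial = session.trial(tid)
                label = trial.stimulus if variable == "stimulus" else trial.choice
                p_true[tid] = p_first if label == first else 1.0 - p_first
        vals = np.array([p_true[t] for t in trial_ids])
        perf_reps.append(vals.mean())
        acc_reps.append(np.mean(np.where(vals > 0.5, 1.0, np.where(vals < 0.5, 0.0, 0.5))))
        for tid in trial_ids:
            post_sum[tid] += p_true[tid]

    perf_reps = np.array(perf_reps)
    acc_reps = np.array(acc_reps)
    rows = []
    for tid in trial_ids:
        trial = session.trial(tid)
        label = trial.stimulus if variable == "stimulus" else trial.choice
        mean_p = post_sum[tid] / reps
        predicted = None
        second = VARIABLE_CONDITIONS[variable][1]
        # mean posterior on the true label -> implied posterior on the first label
        p_first = mean_p if label == first else 1.0 - mean_p
        if p_first > 0.5:
            predicted = first
        elif p_first < 0.5:
            predicted = second
        rows.append(
            {
                "trial_id": tid,
                "variable": variable,
                "final_posterior_true": mean_p,
                "predicted": predicted,
                "true_label": label,
            }
        )
    table = pd.DataFrame(rows)
    summary = PerformanceSummary(
        variable=variable,
        mean_performance=float(perf_reps.mean()),
        accuracy=float(acc_reps.mean()),
        performance_reps=perf_reps,
        accuracy_reps=acc_reps,
        n_trials=len(trial_ids),
        n_reps=reps,
        folds=folds_eff,
        units=tuple(units),
    )
    return summary, table


def decode_unit(
    session: Session,
    unit: str,
    variable: str = "stimulus",
    folds: int = 10,
    reps: int = 124,
    seed: int | None = None,
    backend=None,
) -> PerformanceSummary:
    """Repeated cross-validated decoding performance of a single unit."""
    backend = backend or ISIDecoderBackend()
    summary, _ = cross_validated_decode(
        session, [unit], variable, backend, folds=folds, reps=reps, seed=seed
    )
    return summary


def decode_ensemble(
    session: Session,
    units: list[str],
    variable: str = "stimulus",
    folds: int = 10,
    reps: int = 124,
    seed: int | None = None,
    backend=None,
) -> PerformanceSummary:
    """Ensemble decoding: a shared posterior updated by every member's ISIs."""
    backend = backend or ISIDecoderBackend()
    summary, _ = cross_validated_decode(
        session, list(units), variable, backend, folds=folds, reps=reps, seed=seed
    )
    return summary


def predict_errors(
    session: Session,
    units: list[str],
    folds: int = 10,
    reps: int = 10,
    seed: int | None = None,
    backend=None,
) -> float | None:
    """Predict behavioral errors from held-out choice decoding.

    Likelihoods are trained on correct trials only.  A held-out trial is
    predicted-error when the decoded choice (posterior > 0.5) mismatches
    the choice its stimulus demands.  Returns the balanced accuracy over
    {correct, error} trials (chance 0.5), or None when the session has no
    error trials.
    """
    backend = backend or ISIDecoderBackend()
    session.assign_windows()
    correct_ids = [t.trial_id for t in session.trials if t.outcome == "correct"]
    error_ids = [t.trial_id for t in session.trials if t.outcome == "error"]
    if not error_ids:
        warnings.warn("session has no error trials; error prediction undefined")
        return None
    rng = np.random.default_rng(seed)
    folds_eff = _effective_folds(session, correct_ids, folds)

    def predicted_error_score(tid: str, models_by_unit) -> float:
        trial = session.trial(tid)
        total = 0.0
        n_updates = 0
        for u in units:
            _, d = backend.trial_updates(models_by_unit[u], session, u, tid)
            total += float(d.sum())
            n_updates += d.size
        if n_updates == 0:
            return 0.5
        p_go = float(_sigmoid(total))
        if p_go == 0.5:
            return 0.5
        decoded = "go" if p_go > 0.5 else "no-go"
        return 1.0 if decoded != demanded_choice(trial.stimulus) else 0.0

    bal_reps = []
    for _ in range(reps):
        fold_of = _stratified_folds(session, correct_ids, folds_eff, rng)
        err_scores, corr_scores = [], []
        for f in range(folds_eff):
            train_ids = [t for t in correct_ids if fold_of[t] != f]
            test_ids = [t for t in correct_ids if fold_of[t] == f]
            models = {u: backend.fit(session, u, train_ids, "choice", rng) for u in units}
            for tid in test_ids:
                corr_scores.append(predicted_error_score(tid, models))
            # error trials are never trained on; decode them in every fold
            for tid in error_ids:
                err_scores.append(predicted_error_score(tid, models))
        sensitivity = float(np.mean(err_scores))
        specificity = 1.0 - float(np.mean(corr_scores))
        bal_reps.append(0.5 * (sensitivity + specificity))
    return float(np.mean(bal_reps))


def compare_to_null(
    perf: PerformanceSummary | np.ndarray, null_perfs: np.ndarray
) -> float:
    """One-sided permutation-style p-value against a null performance set.

    The observed summary is the median of the bootstrap repetitions;
    p = (1 + #{null >= observed}) / (1 + N_null), so the floor with 1240
    null repetitions is 1/1241.
    """
    null_perfs = np.asarray(null_perfs, dtype=float)
    if null_perfs.size == 0:
        raise ValueError("null_perfs must be non-empty")
    if isinstance(perf, PerformanceSummary):
        observed = float(np.median(perf.performance_reps))
    else:
        observed = float(np.median(np.asarray(perf, dtype=float)))
    return float((1 + np.count_nonzero(null_perfs >= observed)) / (1 + null_perfs.size))
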