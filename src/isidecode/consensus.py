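"""Ensemble agreement of (weighted) log-likelihood-ratio functions.

A local ensemble "reaches consensus" when its members assign the same
task-variable meaning to the same ISIs.  The consensus of n LLR curves is

    consensus = ||Σ_i LLR_i||_1 / Σ_i ||LLR_i||_1

with the l1 norm taken as the absolute area under the curve, so identical
members give 1 and sign-reversed members cancel to 0.  The unsigned
consensus maximizes the same quantity over every sign assignment of the
members up to a global sign (2^(n-1) combinations, enumerated exactly):
members that partition the ISI axis the same way but disagree about which
side means target still score 1.

Time courses recompute per-member weighted LLRs in a 750 ms sliding window
stepped every 100 ms, aligned either to the stimulus or to the behavioral
response, and assign each window's consensus to its center.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .density import (
    BANDWIDTH_GRID,
    GaussianKDE,
    LLRFunction,
    cv_bandwidth,
    default_grid,
)
from .session import Session, extract_isis

__all__ = [
    "ConsensusResult",
    "ConsensusTimecourse",
    "l1_norm",
    "consensus",
    "unsigned_consensus",
    "consensus_timecourse",
    "interpolate_timecourse",
    "UNSIGNED_ENUMERATION_CAP",
]

#: full enumeration of sign assignments is capped at 2^15 patterns
UNSIGNED_ENUMERATION_CAP = 16


@dataclass
class ConsensusResult:
    value: float
    n_members: int
    norm_kind: str = "l1"
    grid: np.ndarray | None = None


@dataclass
class ConsensusTimecourse:
    alignment: str
    centers: np.ndarray
    values: np.ndarray
    window_length: float = 0.75
    step: float = 0.1


def _curve(llr: LLRFunction | np.ndarray, weighted: bool) -> np.ndarray:
    if isinstance(llr, LLRFunction):
        return llr.weighted_values if weighted else llr.llr_values
    return np.asarray(llr, dtype=float)


def _grid_of(llr: LLRFunction | np.ndarray, fallback: np.ndarray | None) -> np.ndarray:
    if isinstance(llr, LLRFunction):
        return np.asarray(llr.grid, dtype=float)
    if fallback is None:
        raise ValueError("a grid is required for bare-array LLRs")
    return fallback


def l1_norm(values: np.ndarray, grid: np.ndarray) -> float:
    """Absolute area under the curve, trapezoidal, on the log-ISI coordinate."""
    x = np.log(np.asarray(grid, dtype=float))
    return float(np.trapezoid(np.abs(np.asarray(values, dtype=float)), x))


def _consensus_of(curves: list[np.ndarray], grid: np.ndarray) -> float | None:
    norms = [l1_norm(c, grid) for c in curves]
    total = sum(norms)
    if total == 0:
        return None
    return l1_norm(np.sum(curves, axis=0), grid) / total


def consensus(
    llrs: list[LLRFunction | np.ndarray],
    grid: np.ndarray | None = None,
    weighted: bool = True,
) -> ConsensusResult:
    """Norm of the sum of members' LLRs over the sum of their norms.

    Bounded in [0, 1] by the triangle inequality; undefined (value NaN)
    when every member is identically zero.
    """
    if len(llrs) < 2:
        raise ValueError("consensus needs at least 2 ensemble members")
    g = _grid_of(llrs[0], grid)
    curves = [_curve(f, weighted) for f in llrs]
    if any(c.shape != curves[0].shape for c in curves):
        raise ValueError("members must share the evaluation grid")
    val = _consensus_of(curves, g)
    return ConsensusResult(float("nan") if val is None else float(val), len(llrs), grid=g)


def unsigned_consensus(
    llrs: list[LLRFunction | np.ndarray],
    grid: np.ndarray | None = None,
    weighted: bool = True,
) -> ConsensusResult:
    """Maximum consensus over member sign flips, up to a global sign.

    Exhaustive over the 2^(n-1) assignments (first member's sign fixed);
    ensembles above the cap raise rather than fall back to a heuristic.
    """
    if len(llrs) < 2:
        raise ValueError("unsigned consensus needs at least 2 ensemble members")
    if len(llrs) > UNSIGNED_ENUMERATION_CAP:
        raise ValueError(
            f"unsigned consensus enumerates 2^(n-1) sign patterns; n={len(llrs)} "
            f"exceeds the cap of {UNSIGNED_ENUMERATION_CAP} — analyze subsets instead"
        )
    g = _grid_of(llrs[0], grid)
    curves = [_curve(f, weighted) for f in llrs]
    best = None
    for signs in product((1.0, -1.0), repeat=len(curves) - 1):
        val = _consensus_of([curves[0]] + [s * c for s, c in zip(signs, curves[1:])], g)
        if val is not None and (best is None or val > best):
            best = val
    return ConsensusResult(float("nan") if best is None else float(best), len(llrs), grid=g)


def interpolate_timecourse(
    tc: ConsensusTimecourse, n: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Third-degree spline through the window values, for plotting only.

    The spline intercepts every measured value; statistics should always
    be computed on the raw window values in ``tc.values``.
    """
    from scipy.interpolate import InterpolatedUnivariateSpline

    if tc.centers.size < 4:
        return tc.centers, tc.values
    xs = np.linspace(tc.centers[0], tc.centers[-1], n)
    spline = InterpolatedUnivariateSpline(tc.centers, tc.values, k=3)
    return xs, spline(xs)


def _window_llr(
    session: Session,
    unit: str,
    variable: str,
    trial_ids: list[str],
    window: tuple[float, float],
    alignment: str,
    grid: np.ndarray,
    min_obs: int,
    rng: np.random.Generator,
    floor: float = 1e-9,
) -> np.ndarray | None:
    """Weighted LLR of one unit from the ISIs whose final spike falls in an
    aligned window; None when either condition lacks observations."""
    from .decoder import VARIABLE_CONDITIONS

    first, second = VARIABLE_CONDITIONS[variable]
    by_cond: dict[str, list[float]] = {first: [], second: []}
    for tid in trial_ids:
        trial = session.trial(tid)
        label = trial.stimulus if variable == "stimulus" else trial.choice
        obs = extract_isis(session.spike_train(unit, tid), (0.0, trial.effective_end))
        shift = 0.0 if alignment == "stimulus" else -trial.effective_end
        for o in obs:
            t_aligned = o.final_spike_time + shift
            if window[0] <= t_aligned < window[1]:
                by_cond[label].append(o.isi)
    if len(by_cond[first]) < min_obs or len(by_cond[second]) < min_obs:
        return None
    support = (np.log(grid[0]), np.log(grid[-1]))
    logx = np.log(grid)
    dens = {}
    for cond, isis in by_cond.items():
        x = np.log(np.asarray(isis))
        kde = GaussianKDE(x, cv_bandwidth(x, BANDWIDTH_GRID, rng=rng), support)
        dens[cond] = np.maximum(kde(logx), floor)
    pooled = np.log(np.asarray(by_cond[first] + by_cond[second]))
    mkde = GaussianKDE(pooled, cv_bandwidth(pooled, BANDWIDTH_GRID, rng=rng), support)
    marginal = np.maximum(mkde(logx), floor)
    return marginal * (np.log2(dens[first]) - np.log2(dens[second]))


def consensus_timecourse(
    session: Session,
    units: list[str],
    variable: str = "stimulus",
    alignment: str = "stimulus",
    correct_only: bool = True,
    window: float = 0.75,
    step: float = 0.1,
    grid: np.ndarray | None = None,
    min_obs: int = 5,
    seed: int | None = None,
) -> ConsensusTimecourse:
    """Consensus of per-window weighted LLRs along the trial.

    Stimulus-aligned windows run forward from tone onset; response-aligned
    windows are indexed by center time relative to the response (negative
    before it).  A window where any member lacks enough ISIs is dropped.
    """
    if alignment not in ("stimulus", "response"):
        raise ValueError("alignment must be 'stimulus' or 'response'")
    session.assign_windows()
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    trial_ids = [
        t.trial_id
        for t in session.trials
        if not correct_only or t.outcome == "correct"
    ]
    max_end = max(t.effective_end for t in session.trials)
    if alignment == "stimulus":
        starts = np.arange(0.0, max(max_end - window, 0.0) + 1e-9, step)
    else:
        starts = np.arange(-max_end, -window + 1e-9, step)
    centers, values = [], []
    for s in starts:
        w = (float(s), float(s + window))
        curves = []
        ok = True
        for u in units:
            c = _window_llr(
                session, u, variable, trial_ids, w, alignment, grid, min_obs, rng
            )
            if c is None:
                ok = False
                break
            curves.append(c)
        if not ok:
            continue
        val = _consensus_of(curves, grid)
        if val is None:
            continue
        centers.append(s + window / 2.0)
        values.append(val)
    return ConsensusTimecourse(
        alignment, np.asarray(centers), np.asarray(values), window, step
    )
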