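"""Conditional ISI likelihoods by kernel density estimation on log-ISI.

The probability of observing an interspike interval given a task condition,
p(ISI | condition, t), is estimated nonparametrically: ISIs from training
trials are pooled into per-condition libraries, mapped to the natural
logarithm of the interval (the ISI domain is positive, the log maps it to
the whole real line), and smoothed with a Gaussian kernel whose bandwidth
is chosen by 10-fold cross-validation.  Non-stationarity within the trial
is handled by re-estimating the density in 1 s sliding windows recalculated
every 100 ms; an ISI is always assessed with the window whose center is
closest to its final spike.

Working on log-ISI for every condition means the Jacobian of the transform
cancels in all likelihood ratios, so densities here are per unit log-ISI
throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import ndtr

from .session import ISIObservation, Session, extract_isis, trial_window

__all__ = [
    "EstimationError",
    "ISILibrary",
    "GaussianKDE",
    "WindowDensity",
    "ConditionalISILikelihood",
    "LLRFunction",
    "default_grid",
    "cv_bandwidth",
    "build_libraries",
    "fit_window_density",
    "assign_window",
    "evaluate_likelihood",
    "compute_llr",
    "DENSITY_FLOOR",
    "BANDWIDTH_GRID",
]

#: density floor applied at evaluation (per log-ISI unit); prevents zero
#: likelihoods for ISIs far outside the fitted support
DENSITY_FLOOR = 1e-9

#: 30 log-spaced candidate kernel bandwidths, in log-ISI units
BANDWIDTH_GRID = np.geomspace(0.01, 1.5, 30)

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def default_grid(n: int = 512, isi_min: float = 1e-3, isi_max: float = 10.0) -> np.ndarray:
    """Standard log-spaced ISI evaluation grid (seconds), 1 ms to 10 s."""
    return np.geomspace(isi_min, isi_max, n)


class EstimationError(RuntimeError):
    """Raised when a density cannot be estimated from the available ISIs."""


@dataclass
class ISILibrary:
    """All ISIs observed on training trials of one condition."""

    condition: str
    observations: list[ISIObservation]

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def isis(self) -> np.ndarray:
        return np.array([o.isi for o in self.observations], dtype=float)

    @property
    def final_times(self) -> np.ndarray:
        return np.array([o.final_spike_time for o in self.observations], dtype=float)


def cv_bandwidth(
    x: np.ndarray,
    bandwidth_grid: np.ndarray | None = None,
    cv_folds: int = 10,
    rng: np.random.Generator | None = None,
    max_cv_samples: int = 300,
) -> float:
    """Bandwidth maximizing the mean held-out log-density under k-fold CV.

    Ties break toward the smaller bandwidth.  With fewer samples than
    folds the split degenerates to leave-one-out.  For large libraries the
    score is computed on a random subsample of ``max_cv_samples`` points
    (the final density is always fitted on all points).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise EstimationError("need at least 2 observations to select a bandwidth")
    if bandwidth_grid is None:
        bandwidth_grid = BANDWIDTH_GRID
    rng = rng or np.random.default_rng()
    if x.size > max_cv_samples:
        x = rng.choice(x, size=max_cv_samples, replace=False)
    n = x.size
    folds = min(cv_folds, n)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[perm] = np.arange(n) % folds
    # mask[i, j]: point j is in point i's training set (a different fold)
    mask = (fold_of[:, None] != fold_of[None, :]).astype(np.float32)
    n_train = mask.sum(axis=1)

    # squared pairwise distances (float32: plenty for bandwidth selection),
    # reused for every candidate bandwidth; kernel exponents are <= 0, so
    # underflow only drives hopeless bandwidths to a -inf score
    x32 = x.astype(np.float32)
    d2 = (x32[:, None] - x32[None, :]) ** 2
    best_h, best_score = None, -np.inf
    with np.errstate(divide="ignore"):
        for h in np.sort(np.asarray(bandwidth_grid, dtype=float)):
            e = np.exp(d2 * np.float32(-0.5 / (h * h))) * mask
            ll = np.log(e.sum(axis=1) / n_train)
            score = float(ll.mean()) - np.log(h) - _LOG_SQRT_2PI
            if score > best_score:  # strict: ties keep the earlier (smaller) bandwidth
                best_score, best_h = score, float(h)
    return best_h


@dataclass
class GaussianKDE:
    """Gaussian-kernel density on log-ISI, renormalized to the support.

    The kernel mass outside ``support`` (log-ISI bounds) is divided out so
    the density integrates to one over the support analytically.
    """

    points: np.ndarray
    bandwidth: float
    support: tuple[float, float]
    _z: float = field(init=False, repr=False)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        a, b = self.support
        h = self.bandwidth
        self._z = float(np.mean(ndtr((b - self.points) / h) - ndtr((a - self.points) / h)))
        if self._z <= 0:
            self._z = 1.0

    def __call__(self, y: np.ndarray | float) -> np.ndarray | float:
        y = np.asarray(y, dtype=float)
        h = self.bandwidth
        k = np.exp(-((y[..., None] - self.points) ** 2) / (2.0 * h * h))
        dens = k.sum(axis=-1) / (self.points.size * h * np.sqrt(2.0 * np.pi) * self._z)
        a, b = self.support
        dens = np.where((y >= a) & (y <= b), dens, 0.0)
        return dens if dens.ndim else float(dens)


@dataclass
class WindowDensity:
    """Fitted density for one sliding window."""

    center: float
    window: tuple[float, float]
    kde: GaussianKDE
    n_obs: int


def build_libraries(
    session: Session, training_trials: list[str] | None = None
) -> dict[str, ISILibrary]:
    """Sort every in-window ISI of the training trials into four libraries.

    Each ISI lands in exactly one stimulus library (target / non-target)
    and one choice library (go / no-go), according to the labels of its
    trial.
    """
    libs: dict[str, list[ISIObservation]] = {
        "target": [], "non-target": [], "go": [], "no-go": []
    }
    ids = set(training_trials) if training_trials is not None else None
    for trial in session.trials:
        if ids is not None and trial.trial_id not in ids:
            continue
        if trial.effective_end is None:
            trial_window(trial, session)
        window = (0.0, trial.effective_end)
        for unit in session.units:
            obs = extract_isis(session.spike_train(unit, trial.trial_id), window)
            libs[trial.stimulus].extend(obs)
            libs[trial.choice].extend(obs)
    out = {}
    for cond, obs in libs.items():
        if len(obs) < 2:
            raise EstimationError(
                f"condition {cond!r} has {len(obs)} ISI(s); at least 2 are required"
            )
        out[cond] = ISILibrary(cond, obs)
    return out


def fit_window_density(
    library: ISILibrary,
    window: tuple[float, float],
    cv_folds: int = 10,
    bandwidth_grid: np.ndarray | None = None,
    support: tuple[float, float] = (1e-3, 10.0),
    rng: np.random.Generator | None = None,
) -> GaussianKDE:
    """Fit the Gaussian-kernel log-ISI density for one sliding window.

    Uses the observations whose final spike falls in ``window``; the
    bandwidth is the CV-grid maximizer of the mean held-out log-density.
    """
    finals = library.final_times
    keep = (finals >= window[0]) & (finals < window[1])
    isis = library.isis[keep]
    if isis.size < 2:
        raise EstimationError("fewer than 2 ISIs in the window and no fallback")
    x = np.log(isis)
    h = cv_bandwidth(x, bandwidth_grid, cv_folds, rng)
    return GaussianKDE(x, h, (np.log(support[0]), np.log(support[1])))


@dataclass
class ConditionalISILikelihood:
    """p(ISI | condition, t): one fitted density per sliding window."""

    condition: str
    windows: list[WindowDensity]
    support: tuple[float, float] = (1e-3, 10.0)
    floor: float = DENSITY_FLOOR

    @property
    def centers(self) -> np.ndarray:
        return np.array([w.center for w in self.windows])

    @classmethod
    def fit(
        cls,
        library: ISILibrary,
        window_layout: list[tuple[float, float, float]],
        cv_folds: int = 10,
        bandwidth_grid: np.ndarray | None = None,
        support: tuple[float, float] = (1e-3, 10.0),
        rng: np.random.Generator | None = None,
        min_window_obs: int | None = None,
    ) -> "ConditionalISILikelihood":
        """Fit all sliding-window densities for one condition.

        A window holding fewer than ``min_window_obs`` (default: the CV
        fold count) observations is pooled symmetrically with neighboring
        time ranges until the minimum is met; if the whole library is
        smaller than that, a single whole-library density is shared by all
        windows.
        """
        rng = rng or np.random.default_rng()
        min_obs = max(2, min_window_obs if min_window_obs is not None else cv_folds)
        finals = library.final_times
        log_isis = np.log(library.isis)
        log_support = (np.log(support[0]), np.log(support[1]))
        if log_isis.size < 2:
            raise EstimationError(f"condition {library.condition!r}: not enough ISIs")

        step = (
            window_layout[1][0] - window_layout[0][0] if len(window_layout) > 1 else 0.1
        )
        windows: list[WindowDensity] = []
        cache: dict[bytes, GaussianKDE] = {}  # identical pooled subsets share one fit
        for (w_start, w_end, w_center) in window_layout:
            lo, hi = w_start, w_end
            keep = (finals >= lo) & (finals < hi)
            # symmetric neighbor pooling until the window holds enough ISIs
            while keep.sum() < min_obs and (lo > finals.min() or hi < finals.max() + step):
                lo, hi = lo - step, hi + step
                keep = (finals >= lo) & (finals < hi)
            if keep.sum() < min_obs:
                keep = np.ones_like(keep)  # whole-library fallback
            key = np.packbits(keep).tobytes()
            kde = cache.get(key)
            if kde is None:
                x = log_isis[keep]
                kde = GaussianKDE(x, cv_bandwidth(x, bandwidth_grid, cv_folds, rng), log_support)
                cache[key] = kde
            windows.append(WindowDensity(w_center, (w_start, w_end), kde, int(keep.sum())))
        return cls(library.condition, windows, support)

    def assign_window(self, final_spike_time: float) -> int:
        return assign_window_centers(final_spike_time, self.centers)

    def evaluate(self, obs: ISIObservation) -> float:
        """Density (per log-ISI) at the observation, window-assigned and floored."""
        w = self.windows[self.assign_window(obs.final_spike_time)]
        return max(float(w.kde(np.log(obs.isi))), self.floor)

    def evaluate_many(self, isis: np.ndarray, finals: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`evaluate` over a trial's ISIs."""
        isis = np.asarray(isis, dtype=float)
        finals = np.asarray(finals, dtype=float)
        idx = np.abs(finals[:, None] - self.centers[None, :])
        which = np.argmin(idx, axis=1)  # argmin takes the first (earlier) on ties
        out = np.empty(isis.size)
        logx = np.log(isis)
        for w in np.unique(which):
            sel = which == w
            out[sel] = self.windows[w].kde(logx[sel])
        return np.maximum(out, self.floor)

    def grid_values(self, grid: np.ndarray) -> np.ndarray:
        """Density values on an ISI grid (seconds), one row per window."""
        logx = np.log(np.asarray(grid, dtype=float))
        return np.vstack([w.kde(logx) for w in self.windows])

    def to_dict(self, grid: np.ndarray | None = None) -> dict:
        grid = default_grid() if grid is None else np.asarray(grid)
        return {
            "condition": self.condition,
            "support": list(self.support),
            "grid": grid.tolist(),
            "windows": [
                {
                    "center": w.center,
                    "window": list(w.window),
                    "bandwidth": w.kde.bandwidth,
                    "n_obs": w.n_obs,
                    "points": w.kde.points.tolist(),
                    "density": np.asarray(w.kde(np.log(grid))).tolist(),
                }
                for w in self.windows
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionalISILikelihood":
        support = tuple(d["support"])
        log_support = (np.log(support[0]), np.log(support[1]))
        windows = [
            WindowDensity(
                w["center"],
                tuple(w["window"]),
                GaussianKDE(np.array(w["points"]), w["bandwidth"], log_support),
                w["n_obs"],
            )
            for w in d["windows"]
        ]
        return cls(d["condition"], windows, support)

    def save(self, path: str | Path, grid: np.ndarray | None = None) -> None:
        Path(path).write_text(json.dumps(self.to_dict(grid)))

    @classmethod
    def load(cls, path: str | Path) -> "ConditionalISILikelihood":
        return cls.from_dict(json.loads(Path(path).read_text()))


def assign_window_centers(final_spike_time: float, centers: np.ndarray) -> int:
    """Index of the window center closest to the final spike (ties and
    out-of-range times clamp to the earlier / nearest window)."""
    if centers.size == 0:
        raise ValueError("no windows")
    return int(np.argmin(np.abs(final_spike_time - centers)))


def assign_window(
    obs: ISIObservation, windows: list[tuple[float, float, float]]
) -> int:
    centers = np.array([w[2] for w in windows])
    return assign_window_centers(obs.final_spike_time, centers)


def evaluate_likelihood(model: ConditionalISILikelihood, obs: ISIObservation) -> float:
    return model.evaluate(obs)


@dataclass
class LLRFunction:
    """Per-window log2 likelihood-ratio curve over the ISI grid.

    Positive values indicate the first-listed condition (target, or go);
    ``weighted_values`` multiplies pointwise by the marginal ISI density so
    rare intervals contribute little.
    """

    grid: np.ndarray
    llr_values: np.ndarray
    weighted_values: np.ndarray
    w_center: float
    variable: str


def compute_llr(
    model_a: ConditionalISILikelihood,
    model_b: ConditionalISILikelihood,
    grid: np.ndarray | None = None,
    marginal: ConditionalISILikelihood | None = None,
    variable: str = "stimulus",
) -> list[LLRFunction]:
    """LLR(ISI) = log2 p(ISI|a) - log2 p(ISI|b), one curve per window.

    Densities are floored before taking logs, so the ratio is finite
    everywhere and swapping the pair negates the curves exactly.  The
    weighted variant multiplies by the marginal (condition-agnostic)
    density, fitted on the pooled library.
    """
    if len(model_a.windows) != len(model_b.windows):
        raise ValueError("models must share the window layout")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    fa = np.maximum(model_a.grid_values(grid), model_a.floor)
    fb = np.maximum(model_b.grid_values(grid), model_b.floor)
    llr = np.log2(fa) - np.log2(fb)
    if marginal is not None:
        fm = np.maximum(marginal.grid_values(grid), marginal.floor)
    else:
        fm = np.ones_like(llr)
    out = []
    for i, w in enumerate(model_a.windows):
        out.append(LLRFunction(grid, llr[i], fm[i] * llr[i], w.center, variable))
    return out
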