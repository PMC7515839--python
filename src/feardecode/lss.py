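"""Single-trial activity estimation by least-squares-separate (LSS) modelling.

Each chunk-first trial gets its own general linear model with three event
regressors — the trial itself, all other chunk-first trials pooled, and all
non-first presentations pooled — plus an intercept.  Runs are linearly
detrended first; the same detrend projection is applied to the event
regressors so the fit is equivalent to including constant+linear drift
columns in every trial model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class DesignError(ValueError):
    """Raised for infeasible or rank-deficient trial models."""


# ---------------------------------------------------------------------------
# Hemodynamics

_HRF_PEAK_SHAPE = 6.0      # gamma shape of the positive lobe (mode at 5 s)
_HRF_UNDER_SHAPE = 16.0    # gamma shape of the undershoot (mode at 15 s)
_HRF_UNDER_RATIO = 1.0 / 6.0
_HRF_DURATION = 32.0       # seconds of support kept for convolution


def canonical_hrf(t: np.ndarray | float) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak-normalized to 1.

    Difference of two gamma densities (unit scale): a positive lobe peaking
    at ~5 s and an undershoot peaking at ~15 s, weighted 1:1/6.  Zero at
    t = 0 and for t < 0.
    """
    t = np.asarray(t, dtype=float)
    h = stats.gamma.pdf(t, _HRF_PEAK_SHAPE) - _HRF_UNDER_RATIO * stats.gamma.pdf(
        t, _HRF_UNDER_SHAPE
    )
    h = np.where(t < 0, 0.0, h)
    # peak value of the unnormalized shape, computed once on a dense grid
    return h / _hrf_peak_value()


_PEAK_CACHE: list[float] = []


def _hrf_peak_value() -> float:
    if not _PEAK_CACHE:
        grid = np.linspace(0, _HRF_DURATION, 32001)
        h = stats.gamma.pdf(grid, _HRF_PEAK_SHAPE) - _HRF_UNDER_RATIO * stats.gamma.pdf(
            grid, _HRF_UNDER_SHAPE
        )
        _PEAK_CACHE.append(float(h.max()))
    return _PEAK_CACHE[0]


def convolve_onsets(
    onsets: np.ndarray,
    amplitudes: np.ndarray,
    n_scans: int,
    tr: float,
    oversample: int = 16,
) -> np.ndarray:
    """HRF-convolved stick function sampled at scan times ``i * tr``.

    Events are impulses (zero duration) placed on an oversampled grid and
    convolved with :func:`canonical_hrf`; the result is read out at the
    scan grid.  Responses extending past the last scan are truncated.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), onsets.shape)
    if onsets.size and onsets.max() >= n_scans * tr:
        raise DesignError(
            f"onset {onsets.max():g} s falls beyond the scan period ({n_scans * tr:g} s)"
        )
    dt = tr / oversample
    n_hi = n_scans * oversample
    sticks = np.zeros(n_hi)
    idx = np.round(onsets / dt).astype(int)
    np.add.at(sticks, idx, amplitudes)
    kernel = canonical_hrf(np.arange(0, _HRF_DURATION + dt, dt))
    hi = np.convolve(sticks, kernel)[:n_hi] * dt
    return hi[::oversample].copy()


# ---------------------------------------------------------------------------
# Detrending

def detrend_linear(timeseries: np.ndarray) -> np.ndarray:
    """Remove the least-squares line (intercept + slope) from each column.

    ``timeseries`` is scans x voxels (a 1-D array is treated as a single
    voxel).  The output has per-run mean ~0 and is orthogonal to [1, t].
    """
    y = np.asarray(timeseries, dtype=float)
    squeeze = y.ndim == 1
    y = np.atleast_2d(y.T).T if squeeze else y
    n = y.shape[0]
    if n < 3:
        raise DesignError(f"need at least 3 scans to detrend, got {n}")
    out = _detrend_projection(n) @ y
    return out[:, 0] if squeeze else out


def _detrend_projection(n_scans: int) -> np.ndarray:
    """Residual-maker matrix for the [1, t] drift basis."""
    t = np.arange(n_scans, dtype=float)
    X = np.column_stack([np.ones(n_scans), t - t.mean()])
    Q, _ = np.linalg.qr(X)
    return np.eye(n_scans) - Q @ Q.T


# ---------------------------------------------------------------------------
# LSS design and fitting

TARGET_COL = "target_trial"
OTHER_FIRST_COL = "other_chunk_first"
NON_FIRST_COL = "non_first_presentations"
INTERCEPT_COL = "intercept"


@dataclass
class DesignMatrix:
    """GLM design for one LSS trial model: scans x regressors."""

    values: np.ndarray
    names: list[str]
    tr: float
    target_trial: int | None = None
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise DesignError("design values/names mismatch")

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]


@dataclass
class TrialBetaMatrix:
    """Per-subject single-trial activity estimates (trials x voxels).

    Rows align with the subject's chunk-first trials in presentation order;
    ``trial_info`` carries (run, presentation, onset, category) per row.
    """

    subject: int
    betas: np.ndarray
    trial_info: pd.DataFrame

    def __post_init__(self) -> None:
        if self.betas.shape[0] != len(self.trial_info):
            raise DesignError("beta rows do not match trial_info")
        if not np.all(np.isfinite(self.betas)):
            raise DesignError("non-finite beta estimates")

    @property
    def n_trials(self) -> int:
        return self.betas.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[1]


def build_lss_design(
    run_trials: pd.DataFrame,
    target_trial: int,
    n_scans: int,
    tr: float,
    oversample: int = 16,
) -> DesignMatrix:
    """Build the LSS design for one chunk-first trial of one run.

    ``run_trials`` holds one run's presentations with columns ``onset``
    (seconds from run start), ``chunk_first`` (bool) and ``presentation``.
    ``target_trial`` is the presentation index of the modelled chunk-first
    trial.  Columns: the target trial's HRF-convolved stick; all other
    chunk-first trials pooled; all non-first presentations pooled; an
    intercept.  All-zero event columns (degenerate designs) are dropped
    with a warning and recorded in ``dropped``.
    """
    run_trials = run_trials.reset_index(drop=True)
    row = run_trials[run_trials["presentation"] == target_trial]
    if len(row) != 1 or not bool(row["chunk_first"].iloc[0]):
        raise DesignError(f"target trial {target_trial} is not a chunk-first trial of this run")
    onset = float(row["onset"].iloc[0])

    firsts = run_trials[run_trials["chunk_first"]]
    others = firsts[firsts["presentation"] != target_trial]
    nonfirst = run_trials[~run_trials["chunk_first"]]

    cols, names = [], []
    cols.append(convolve_onsets([onset], [1.0], n_scans, tr, oversample))
    names.append(TARGET_COL)
    for frame, name in ((others, OTHER_FIRST_COL), (nonfirst, NON_FIRST_COL)):
        col = convolve_onsets(
            frame["onset"].to_numpy(), np.ones(len(frame)), n_scans, tr, oversample
        ) if len(frame) else np.zeros(n_scans)
        cols.append(col)
        names.append(name)
    cols.append(np.ones(n_scans))
    names.append(INTERCEPT_COL)

    values = np.column_stack(cols)
    dropped = []
    keep = np.ones(values.shape[1], dtype=bool)
    for j, name in enumerate(names):
        if name != INTERCEPT_COL and not np.any(values[:, j]):
            keep[j] = False
            dropped.append(name)
    if dropped:
        warnings.warn(
            f"dropping all-zero regressor(s) {dropped} for trial {target_trial}",
            stacklevel=2,
        )
        values = values[:, keep]
        names = [n for n, k in zip(names, keep) if k]
    if np.linalg.matrix_rank(values) < values.shape[1]:
        raise DesignError(f"rank-deficient design for trial {target_trial}")
    return DesignMatrix(values, names, tr, target_trial=target_trial, dropped=dropped)


def fit_lss_trial(timeseries: np.ndarray, design: DesignMatrix) -> np.ndarray:
    """Ordinary least squares; returns the target-trial coefficient per voxel."""
    y = np.atleast_2d(np.asarray(timeseries, dtype=float).T).T
    if y.shape[0] != design.n_scans:
        raise DesignError(
            f"timeseries has {y.shape[0]} scans but design expects {design.n_scans}"
        )
    if TARGET_COL not in design.names:
        raise DesignError("design has no target-trial column")
    coef, _, rank, _ = np.linalg.lstsq(design.values, y, rcond=None)
    if rank < design.values.shape[1]:
        raise DesignError(f"rank-deficient fit for trial {design.target_trial}")
    return coef[design.names.index(TARGET_COL)]


def estimate_all_betas(
    run_series: dict[int, np.ndarray],
    trials: pd.DataFrame,
    tr: float,
    subject: int = 0,
    oversample: int = 16,
    detrend_regressors: bool = True,
) -> TrialBetaMatrix:
    """Detrend each run, then fit one LSS model per chunk-first trial.

    ``run_series`` maps run index to a scans x voxels array; ``trials`` is
    the subject's schedule (columns run, presentation, onset, chunk_first,
    category).  The drift projection used on the data is also applied to
    the event regressors (equivalent to drift columns in each model), so
    noiseless signals are recovered without detrending bias.
    """
    rows, info = [], []
    for run in sorted(run_series):
        series = np.atleast_2d(np.asarray(run_series[run], dtype=float).T).T
        run_trials = trials[trials["run"] == run]
        if run_trials.empty:
            raise DesignError(f"no trials for run {run}")
        n_scans = series.shape[0]
        R = _detrend_projection(n_scans)
        y = R @ series
        for _, trial in run_trials[run_trials["chunk_first"]].iterrows():
            design = build_lss_design(
                run_trials, int(trial["presentation"]), n_scans, tr, oversample
            )
            if detrend_regressors:
                values = design.values.copy()
                for j, name in enumerate(design.names):
                    if name != INTERCEPT_COL:
                        values[:, j] = R @ values[:, j]
                design = DesignMatrix(
                    values, design.names, tr, design.target_trial, design.dropped
                )
            rows.append(fit_lss_trial(y, design))
            info.append(
                {
                    "run": int(run),
                    "presentation": int(trial["presentation"]),
                    "onset": float(trial["onset"]),
                    "category": int(trial.get("category", -1)),
                }
            )
    return TrialBetaMatrix(subject, np.vstack(rows), pd.DataFrame(info))
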