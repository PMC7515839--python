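"""Skin-conductance reactivity scoring and the group-level coupling check.

A trial's reactivity is the maximum conductance in a 1-5 s window after
image onset minus the mean baseline in the 2 s before onset.  Responses
below 0.2 uS are recoded to 0 and surviving amplitudes are square-root
transformed to correct the right skew.  Reactivity is scored only for the
first image of each chunk.  The group-level procedure drops the first
chunk-first trial of every run, winsorizes, averages within category,
standardizes, and correlates the group category means with the equally
processed fear ratings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SCR_FLOOR = 0.2  # uS; smaller deflections are recoded as no response
PEAK_WINDOW = (1.0, 5.0)  # seconds after onset, (open, closed]
BASELINE_WINDOW = 2.0  # seconds before onset, [closed, open)
_EPS = 1e-9


class TraceBoundaryError(ValueError):
    """Raised when a scoring window falls outside the recorded trace."""


@dataclass(frozen=True)
class SCRTrace:
    """A continuous electrodermal recording for one run.

    ``samples`` in microsiemens at ``rate`` Hz, starting at ``start``
    seconds on the run clock (typically negative so the first trial has a
    full baseline window).
    """

    samples: np.ndarray
    rate: float
    start: float = 0.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return self.start + np.arange(len(self.samples)) / self.rate

    @property
    def end(self) -> float:
        return self.start + (len(self.samples) - 1) / self.rate


def score_trial(trace: SCRTrace, onset: float) -> float:
    """Raw reactivity: peak in (onset+1, onset+5] minus mean of [onset-2, onset).

    May be negative at this stage; thresholding happens separately.
    """
    if onset - BASELINE_WINDOW < trace.start - _EPS or onset + PEAK_WINDOW[1] > trace.end + _EPS:
        raise TraceBoundaryError(
            f"scoring windows for onset {onset:g} s fall outside the trace "
            f"[{trace.start:g}, {trace.end:g}] s"
        )
    t = trace.times - onset
    peak_mask = (t > PEAK_WINDOW[0] + _EPS) & (t <= PEAK_WINDOW[1] + _EPS)
    base_mask = (t >= -BASELINE_WINDOW - _EPS) & (t < -_EPS)
    if not peak_mask.any() or not base_mask.any():
        raise TraceBoundaryError(f"no samples in scoring windows for onset {onset:g} s")
    return float(trace.samples[peak_mask].max() - trace.samples[base_mask].mean())


def threshold_and_transform(raw: float | np.ndarray) -> np.ndarray | float:
    """Recode responses below 0.2 uS (incl. negative deflections) to 0, then sqrt."""
    raw = np.asarray(raw, dtype=float)
    out = np.where(raw < SCR_FLOOR, 0.0, np.sqrt(np.maximum(raw, 0.0)))
    return float(out) if out.ndim == 0 else out


def score_design(traces: dict[int, SCRTrace], trials: pd.DataFrame) -> pd.DataFrame:
    """Score every chunk-first trial of a subject's schedule.

    ``traces`` maps run index to that run's trace; ``trials`` holds the
    presentation schedule (columns run, presentation, onset, chunk_first,
    category).  Returns one row per chunk-first trial with raw,
    thresholded and sqrt-transformed amplitudes.
    """
    rows = []
    for _, trial in trials[trials["chunk_first"]].iterrows():
        run = int(trial["run"])
        if run not in traces:
            raise TraceBoundaryError(f"no trace for run {run}")
        try:
            raw = score_trial(traces[run], float(trial["onset"]))
        except TraceBoundaryError as err:
            raise TraceBoundaryError(
                f"run {run}, presentation {int(trial['presentation'])}: {err}"
            ) from err
        thresholded = 0.0 if raw < SCR_FLOOR else raw
        rows.append(
            {
                "run": run,
                "presentation": int(trial["presentation"]),
                "onset": float(trial["onset"]),
                "category": int(trial.get("category", -1)),
                "raw": raw,
                "thresholded": thresholded,
                "transformed": float(threshold_and_transform(raw)),
            }
        )
    columns = ["run", "presentation", "onset", "category", "raw", "thresholded", "transformed"]
    return pd.DataFrame(rows, columns=columns)


def winsorize(values: np.ndarray, lower: float = 5.0, upper: float = 95.0) -> np.ndarray:
    """Clamp values outside the given percentiles (linear-interpolation rule)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("winsorizing needs at least 2 values")
    lo, hi = np.percentile(values, [lower, upper])
    return np.clip(values, lo, hi)


def _zscore(values: np.ndarray, context: str = "") -> np.ndarray:
    sd = np.std(values, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        logger.warning("zero-variance standardization%s; returning zeros",
                       f" ({context})" if context else "")
        warnings.warn(f"zero-variance standardization {context}".strip(), stacklevel=3)
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def drop_run_first(table: pd.DataFrame) -> pd.DataFrame:
    """Drop the first chunk-first trial of each run (atypically large SCR)."""
    first = table.groupby("run")["presentation"].transform("min")
    return table[table["presentation"] != first]


def category_means(
    tables: dict[int, pd.DataFrame],
    value_col: str = "transformed",
    drop_first: bool = True,
) -> pd.DataFrame:
    """Per-subject standardized category means of a trial-level measure.

    For each subject: drop the first chunk-first trial of each run (6 at
    the default design), winsorize the remaining values at the 5th/95th
    percentile, average within category, and z-score across categories.
    Categories with no remaining trials are left as NaN (excluded pairwise
    downstream).  Returns a subjects x categories frame.
    """
    out = {}
    for subject, table in tables.items():
        t = drop_run_first(table) if drop_first else table
        if t.empty:
            raise ValueError(f"subject {subject} has no scoreable trials")
        vals = pd.Series(winsorize(t[value_col].to_numpy()), index=t.index)
        means = vals.groupby(t["category"]).mean()
        z = _zscore(means.to_numpy(), context=f"subject {subject} category means")
        out[subject] = pd.Series(z, index=means.index)
    frame = pd.DataFrame(out).T
    frame.index.name = "subject"
    frame.columns.name = "category"
    return frame


def group_category_vector(per_subject: pd.DataFrame) -> np.ndarray:
    """Average standardized category means across subjects, then z-score."""
    return _zscore(per_subject.mean(axis=0, skipna=True).to_numpy(), "group category means")


def group_level_correlation(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Pearson correlation of two group category vectors, with Fisher CI.

    Returns r, the two-sided p (df = n-2), the Fisher-z 95% CI, and R^2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 paired categories, got {n}")
    r, p = stats.pearsonr(x, y)
    if abs(r) < 1 and n > 3:
        z = np.arctanh(r)
        half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    else:
        ci = (float(r), float(r))
    return {"r": float(r), "p": float(p), "ci_low": ci[0], "ci_high": ci[1],
            "r2": float(r**2), "n": int(n), "df": int(n - 2)}
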