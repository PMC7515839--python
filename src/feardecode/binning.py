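"""Within-subject binned (averaged) beta images by rating and by SCR level.

Fear binning averages trials sharing a rating level 0-5.  SCR binning puts
sub-0.2 uS trials at level 0 and splits the remaining trials into
within-subject quintiles (levels 1-5); the level-0 image averages a random
subsample of level-0 trials whose size matches the (rounded mean) quintile
bin size, so level 0 is not over-represented.  Binned images are mean
centered within subject.  Categorical mean images drop the first
chunk-first trial of each run and average within animal category.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lss import TrialBetaMatrix
from .scr import SCR_FLOOR, drop_run_first

logger = logging.getLogger(__name__)


class BinningError(ValueError):
    pass


@dataclass
class SubjectBins:
    """One subject's binned images: levels x voxels plus per-level counts."""

    subject: int
    images: np.ndarray
    levels: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.images) == len(self.levels) == len(self.counts)):
            raise BinningError("bins misaligned")


@dataclass
class BinnedDataset:
    """Binned images for one outcome across subjects.

    ``outcome`` is "fear" or "scr"; ``flagged`` lists subjects excluded
    from binning (e.g. too few suprathreshold SCR trials).
    """

    outcome: str
    bins: dict[int, SubjectBins]
    centered: bool = False
    flagged: dict[int, str] = field(default_factory=dict)

    @property
    def subjects(self) -> list[int]:
        return sorted(self.bins)

    def stacked(self, subjects=None):
        """(images, levels, subject_ids) stacked over subjects."""
        subjects = self.subjects if subjects is None else subjects
        X = np.vstack([self.bins[s].images for s in subjects])
        y = np.concatenate([self.bins[s].levels for s in subjects])
        sid = np.concatenate(
            [np.full(len(self.bins[s].levels), s) for s in subjects]
        )
        return X, y, sid


def bin_by_rating(betas: TrialBetaMatrix, trial_ratings: np.ndarray) -> SubjectBins:
    """Average trials sharing a fear rating level; absent levels omitted."""
    ratings = np.asarray(trial_ratings)
    if len(ratings) != betas.n_trials:
        raise BinningError("one rating per chunk-first trial required")
    if betas.n_trials == 0:
        raise BinningError("no trials to bin")
    levels = np.unique(ratings)
    images = np.vstack([betas.betas[ratings == lv].mean(axis=0) for lv in levels])
    counts = np.array([(ratings == lv).sum() for lv in levels])
    return SubjectBins(betas.subject, images, levels.astype(int), counts)


def scr_levels(transformed: np.ndarray) -> np.ndarray:
    """Assign SCR levels 0-5 per trial from sqrt-transformed amplitudes.

    Zeros (sub-floor trials) are level 0; suprathreshold trials are split
    at the within-subject {20,40,60,80}% linear-interpolation percentiles
    into levels 1-5, ties going to the lower level.  Raises if fewer than
    5 suprathreshold trials (quintiles undefined).
    """
    v = np.asarray(transformed, dtype=float)
    levels = np.zeros(v.size, dtype=int)
    pos = v > 0
    if pos.sum() < 5:
        raise BinningError(
            f"only {int(pos.sum())} suprathreshold trials; cannot form quintiles"
        )
    edges = np.percentile(v[pos], [20, 40, 60, 80])
    levels[pos] = 1 + np.searchsorted(edges, v[pos], side="left")
    return levels


def bin_by_scr(
    betas: TrialBetaMatrix, levels: np.ndarray, rng: np.random.Generator
) -> SubjectBins:
    """Average levels 1-5 as-is; level 0 averages a random subsample of
    level-0 trials sized like a quintile bin (rounded mean of the five)."""
    levels = np.asarray(levels)
    if len(levels) != betas.n_trials:
        raise BinningError("one level per trial required")
    out_levels, images, counts = [], [], []
    quint_sizes = [int((levels == lv).sum()) for lv in range(1, 6) if (levels == lv).sum()]
    if not quint_sizes:
        raise BinningError("no suprathreshold levels present")
    target0 = int(round(np.mean(quint_sizes)))
    zero_idx = np.flatnonzero(levels == 0)
    if zero_idx.size:
        if zero_idx.size < target0:
            warnings.warn(
                f"subject {betas.subject}: only {zero_idx.size} level-0 trials "
                f"for a target subsample of {target0}; using all",
                stacklevel=2,
            )
            take = zero_idx
        else:
            take = rng.choice(zero_idx, size=target0, replace=False)
        out_levels.append(0)
        images.append(betas.betas[take].mean(axis=0))
        counts.append(len(take))
    for lv in range(1, 6):
        mask = levels == lv
        if mask.any():
            out_levels.append(lv)
            images.append(betas.betas[mask].mean(axis=0))
            counts.append(int(mask.sum()))
    return SubjectBins(betas.subject, np.vstack(images), np.array(out_levels), np.array(counts))


def center_within_subject(bins: SubjectBins) -> SubjectBins:
    """Subtract the subject's voxelwise mean across binned images."""
    if len(bins.images) < 2:
        raise BinningError(
            f"subject {bins.subject} has a single binned image; centering would annihilate it"
        )
    centered = bins.images - bins.images.mean(axis=0, keepdims=True)
    return SubjectBins(bins.subject, centered, bins.levels.copy(), bins.counts.copy())


def build_binned_dataset(
    betas: dict[int, TrialBetaMatrix],
    labels: dict[int, np.ndarray],
    outcome: str,
    rng: np.random.Generator | None = None,
    center: bool = True,
) -> BinnedDataset:
    """Bin every subject by the given outcome and mean-center within subject.

    ``labels`` maps subject to per-trial ratings (fear) or sqrt-transformed
    SCR values (scr).  Subjects that cannot be binned are flagged and
    skipped (e.g. too few suprathreshold SCR trials).
    """
    if outcome not in ("fear", "scr"):
        raise BinningError(f"unknown outcome {outcome!r}")
    if outcome == "scr" and rng is None:
        raise BinningError("scr binning requires an rng for the level-0 subsample")
    bins: dict[int, SubjectBins] = {}
    flagged: dict[int, str] = {}
    for subject in sorted(betas):
        if subject not in labels:
            flagged[subject] = "no labels"
            continue
        try:
            if outcome == "fear":
                b = bin_by_rating(betas[subject], labels[subject])
            else:
                lv = scr_levels(labels[subject])
                b = bin_by_scr(betas[subject], lv, rng)
            bins[subject] = center_within_subject(b) if center else b
        except BinningError as err:
            logger.warning("subject %s skipped for %s binning: %s", subject, outcome, err)
            flagged[subject] = str(err)
    if not bins:
        raise BinningError(f"no subject could be binned for outcome {outcome!r}")
    return BinnedDataset(outcome, bins, centered=center, flagged=flagged)


def categorical_means(
    betas: TrialBetaMatrix, n_categories: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Category-mean beta images after dropping each run's first chunk-first
    trial (6 trials at the default design).  Returns (images, category ids);
    empty categories are omitted (flagged via the returned ids)."""
    info = betas.trial_info.copy()
    info["row"] = np.arange(len(info))
    kept = drop_run_first(info)
    cats = np.sort(kept["category"].unique())
    images = np.vstack(
        [betas.betas[kept[kept["category"] == c]["row"].to_numpy()].mean(axis=0) for c in cats]
    )
    if n_categories is not None and len(cats) < n_categories:
        logger.warning(
            "subject %s: %d of %d categories empty after run-first removal",
            betas.subject, n_categories - len(cats), n_categories,
        )
    return images, cats
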