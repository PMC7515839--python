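"""Whole-brain linear SVR decoders with leave-one-subject-out evaluation.

Decoders are epsilon-insensitive linear support vector regressions trained
on the mean-centered binned images of N-1 subjects and tested on the
held-out subject, iterated over all subjects so every image receives a
prediction from a model that never saw its subject.  Sensitivity is the
concordance AUC of the pooled predictions (probability that a higher-level
image receives a higher prediction; the ROC AUC in the binary case), with
significance from a within-subject label-permutation null.  Specificity is
probed by cross-decoding (testing each decoder on the other outcome's
dataset), and frozen decoders can be applied to a held-out cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVR

from .binning import BinnedDataset
from .config import DecoderConfig
from .scr import winsorize, _zscore, group_level_correlation


class DecodingError(ValueError):
    pass


class LeakageError(RuntimeError):
    """A subject's data reached a decoder trained on that subject."""


@dataclass
class LinearDecoder:
    """Affine voxel-space decoder: prediction = w . x + b.

    Training-fold feature standardization is folded into ``w``/``b`` so the
    decoder is a plain linear map on raw images.
    """

    w: np.ndarray
    b: float
    outcome: str
    train_subjects: tuple[int, ...]
    hyper: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.w)) or not np.isfinite(self.b):
            raise DecodingError("non-finite decoder weights")


@dataclass
class DecodingResult:
    """Pooled LOSO predictions and their AUC summary."""

    outcome: str
    predictions: pd.DataFrame  # subject, level, prediction
    auc: float
    fold_decoders: dict[int, LinearDecoder] = field(default_factory=dict)
    null: np.ndarray | None = None
    critical_value: float | None = None
    p: float | None = None


def train_decoder(
    X: np.ndarray,
    y: np.ndarray,
    outcome: str = "fear",
    train_subjects: tuple[int, ...] = (),
    config: DecoderConfig = DecoderConfig(),
) -> LinearDecoder:
    """Fit a linear epsilon-insensitive SVR on voxel features.

    Features are voxelwise z-scored with training statistics (constant
    voxels left unscaled); the scaling is folded back into the returned
    weight vector so prediction is ``w . x + b`` on raw images.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise DecodingError("X must be images x voxels aligned with y")
    if len(X) == 0:
        raise DecodingError("empty training set")
    if np.unique(y).size < 2:
        raise DecodingError("training labels are constant")
    if config.scale_features:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
    else:
        mean = np.zeros(X.shape[1])
        sd = np.ones(X.shape[1])
    model = SVR(kernel="linear", C=config.C, epsilon=config.epsilon)
    model.fit((X - mean) / sd, y)
    coef = model.coef_.ravel()
    w = coef / sd
    b = float(model.intercept_[0] - np.dot(coef, mean / sd))
    return LinearDecoder(
        w, b, outcome, tuple(int(s) for s in train_subjects),
        hyper={"C": config.C, "epsilon": config.epsilon, "scaled": config.scale_features},
    )


def predict(decoder: LinearDecoder, images: np.ndarray) -> np.ndarray:
    """Affine map w . x + b per image."""
    images = np.atleast_2d(np.asarray(images, dtype=float))
    if images.shape[1] != decoder.w.size:
        raise DecodingError(
            f"image width {images.shape[1]} != weight length {decoder.w.size}"
        )
    return images @ decoder.w + decoder.b


def auc_concordance(predictions: np.ndarray, levels: np.ndarray) -> float:
    """Pairwise concordance of predictions with ordinal levels.

    Over all pairs with different levels, the fraction where the
    higher-level item received the higher prediction; prediction ties
    count 0.5.  Equals the ROC AUC for binary levels.
    """
    predictions = np.asarray(predictions, dtype=float)
    levels = np.asarray(levels)
    uniq = np.unique(levels)
    if uniq.size < 2:
        raise DecodingError("need at least two distinct levels for AUC")
    num = 0.0
    den = 0
    for i in range(uniq.size):
        for j in range(i + 1, uniq.size):
            lo = predictions[levels == uniq[i]]
            hi = predictions[levels == uniq[j]]
            # Mann-Whitney via average ranks (ties count 0.5)
            combined = np.concatenate([lo, hi])
            ranks = stats.rankdata(combined)
            u = ranks[len(lo):].sum() - len(hi) * (len(hi) + 1) / 2
            num += u
            den += len(lo) * len(hi)
    return float(num / den)


def permutation_null(
    predictions: np.ndarray,
    levels: np.ndarray,
    subjects: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> dict:
    """Within-subject label-permutation null for the concordance AUC.

    Labels are shuffled within each subject and the AUC recomputed on the
    fixed predictions (no retraining).  Returns the null distribution, the
    95th-percentile critical value, and the add-one permutation p-value
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    predictions = np.asarray(predictions, dtype=float)
    levels = np.asarray(levels)
    subjects = np.asarray(subjects)
    if n_perm < 1:
        raise DecodingError("n_perm must be >= 1")
    observed = auc_concordance(predictions, levels)
    groups = [np.flatnonzero(subjects == s) for s in np.unique(subjects)]
    null = np.empty(n_perm)
    perm = levels.copy()
    for k in range(n_perm):
        for idx in groups:
            perm[idx] = levels[idx][rng.permutation(idx.size)]
        null[k] = auc_concordance(predictions, perm)
    # critical value as the order statistic consistent with the add-one p:
    # obs > critical  <=>  p <= 0.05 (up to ties, conservatively)
    k = min(int(np.ceil(0.95 * (n_perm + 1))), n_perm) - 1
    critical = float(np.sort(null)[k])
    p = float((1 + np.sum(null >= observed)) / (n_perm + 1))
    return {"observed": observed, "null": null, "critical_value": critical, "p": p}


def loso_cv(
    dataset: BinnedDataset,
    config: DecoderConfig = DecoderConfig(),
    n_perm: int = 0,
    rng: np.random.Generator | None = None,
) -> DecodingResult:
    """Leave-one-subject-out cross-validated decoding of one outcome."""
    subjects = dataset.subjects
    if len(subjects) < 3:
        raise DecodingError(f"LOSO needs >= 3 subjects, got {len(subjects)}")
    rows = []
    fold_decoders: dict[int, LinearDecoder] = {}
    for held_out in subjects:
        train = [s for s in subjects if s != held_out]
        X, y, _ = dataset.stacked(train)
        dec = train_decoder(X, y, dataset.outcome, tuple(train), config)
        fold_decoders[held_out] = dec
        test = dataset.bins[held_out]
        preds = predict(dec, test.images)
        for lv, pr in zip(test.levels, preds):
            rows.append({"subject": held_out, "level": int(lv), "prediction": float(pr)})
    frame = pd.DataFrame(rows)
    auc = auc_concordance(frame["prediction"].to_numpy(), frame["level"].to_numpy())
    result = DecodingResult(dataset.outcome, frame, auc, fold_decoders)
    if n_perm:
        if rng is None:
            raise DecodingError("permutation test requires an rng")
        stats = permutation_null(
            frame["prediction"].to_numpy(), frame["level"].to_numpy(),
            frame["subject"].to_numpy(), n_perm, rng,
        )
        result.null = stats["null"]
        result.critical_value = stats["critical_value"]
        result.p = stats["p"]
    return result


def audit_no_leakage(result: DecodingResult) -> bool:
    """True iff no pooled prediction came from a decoder trained on its subject."""
    for subject, dec in result.fold_decoders.items():
        if subject in dec.train_subjects:
            return False
    predicted = set(result.predictions["subject"].unique())
    return predicted <= set(result.fold_decoders)


def cross_decode(
    fold_decoders: dict[int, LinearDecoder],
    other_dataset: BinnedDataset,
    n_perm: int = 0,
    rng: np.random.Generator | None = None,
) -> DecodingResult:
    """Test one outcome's fold decoders on the other outcome's dataset.

    Each subject's images are predicted by the decoder from the fold that
    held that subject out, so training subjects never overlap the test
    subject; a violation raises :class:`LeakageError`.
    """
    rows = []
    used: dict[int, LinearDecoder] = {}
    for subject in other_dataset.subjects:
        if subject not in fold_decoders:
            raise DecodingError(
                f"no held-out decoder for subject {subject}; cannot cross-decode without leakage"
            )
        dec = fold_decoders[subject]
        if subject in dec.train_subjects:
            raise LeakageError(f"decoder for subject {subject} was trained on that subject")
        used[subject] = dec
        test = other_dataset.bins[subject]
        preds = predict(dec, test.images)
        for lv, pr in zip(test.levels, preds):
            rows.append({"subject": subject, "level": int(lv), "prediction": float(pr)})
    frame = pd.DataFrame(rows)
    auc = auc_concordance(frame["prediction"].to_numpy(), frame["level"].to_numpy())
    result = DecodingResult(
        f"cross:{next(iter(used.values())).outcome}->{other_dataset.outcome}",
        frame, auc, used,
    )
    if n_perm:
        if rng is None:
            raise DecodingError("permutation test requires an rng")
        stats = permutation_null(
            frame["prediction"].to_numpy(), frame["level"].to_numpy(),
            frame["subject"].to_numpy(), n_perm, rng,
        )
        result.null = stats["null"]
        result.critical_value = stats["critical_value"]
        result.p = stats["p"]
    return result


def predict_categorical(
    fold_decoders: dict[int, LinearDecoder],
    categorical_images: dict[int, tuple[np.ndarray, np.ndarray]],
    group_outcome_by_category: pd.Series,
) -> dict[str, float]:
    """Group-level correlation between decoder predictions of categorical
    mean images and the outcome's category means.

    Per subject: the held-out fold decoder predicts the ~30 category mean
    images; predictions are winsorized (5th/95th pct) and z-scored within
    subject.  At the group level, predictions are averaged per category,
    z-scored, and correlated with the (z-scored) outcome category vector.
    """
    per_subject = {}
    for subject, (images, cats) in categorical_images.items():
        if subject not in fold_decoders:
            raise DecodingError(f"no held-out decoder for subject {subject}")
        dec = fold_decoders[subject]
        if subject in dec.train_subjects:
            raise LeakageError(f"decoder for subject {subject} was trained on that subject")
        preds = predict(dec, images)
        z = _zscore(winsorize(preds), context=f"subject {subject} categorical predictions")
        per_subject[subject] = pd.Series(z, index=cats)
    frame = pd.DataFrame(per_subject).T
    group_pred = _zscore(frame.mean(axis=0, skipna=True).to_numpy(), "group categorical predictions")
    outcome = group_outcome_by_category.reindex(frame.columns).to_numpy()
    return group_level_correlation(group_pred, outcome)


def apply_to_cohort(
    decoder: LinearDecoder,
    cohort_dataset: BinnedDataset,
    n_perm: int = 0,
    rng: np.random.Generator | None = None,
) -> DecodingResult:
    """Apply one frozen decoder (trained on the full discovery cohort) to a
    held-out cohort's binned dataset; no refitting."""
    rows = []
    for subject in cohort_dataset.subjects:
        test = cohort_dataset.bins[subject]
        preds = predict(decoder, test.images)
        for lv, pr in zip(test.levels, preds):
            rows.append({"subject": subject, "level": int(lv), "prediction": float(pr)})
    frame = pd.DataFrame(rows)
    auc = auc_concordance(frame["prediction"].to_numpy(), frame["level"].to_numpy())
    result = DecodingResult(f"cohort:{decoder.outcome}", frame, auc)
    if n_perm:
        if rng is None:
            raise DecodingError("permutation test requires an rng")
        stats = permutation_null(
            frame["prediction"].to_numpy(), frame["level"].to_numpy(),
            frame["subject"].to_numpy(), n_perm, rng,
        )
        result.null = stats["null"]
        result.critical_value = stats["critical_value"]
        result.p = stats["p"]
    return result


def evaluate_single_trial(
    fold_decoders: dict[int, LinearDecoder],
    trial_images: dict[int, np.ndarray],
    trial_labels: dict[int, np.ndarray],
) -> DecodingResult:
    """Test binned-trained decoders on unaveraged single-trial images.

    Trial images are mean-centered within subject (matching the centered
    binned training space) and predicted by the subject's held-out fold
    decoder; pooled predictions are summarized by the concordance AUC.
    """
    rows = []
    used = {}
    for subject, images in trial_images.items():
        if subject not in fold_decoders:
            continue
        dec = fold_decoders[subject]
        if subject in dec.train_subjects:
            raise LeakageError(f"decoder for subject {subject} was trained on that subject")
        used[subject] = dec
        centered = images - images.mean(axis=0, keepdims=True)
        preds = predict(dec, centered)
        for lv, pr in zip(trial_labels[subject], preds):
            rows.append({"subject": subject, "level": int(lv), "prediction": float(pr)})
    frame = pd.DataFrame(rows)
    auc = auc_concordance(frame["prediction"].to_numpy(), frame["level"].to_numpy())
    return DecodingResult("single-trial", frame, auc, used)
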