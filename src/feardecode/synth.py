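"""Synthetic cohort generator.

Emulates the statistical structure the decoding analysis assumes, so every
downstream stage can be exercised without access to the original fMRI/EDA
recordings: a chunked rapid event-related presentation schedule (six runs
of 600 presentations in chunks of 2/3/4/6 images of one animal category,
one presentation per 2 s TR), offline ordinal fear ratings per subject and
category, zero-inflated skin-conductance amplitudes coupled to the
ratings, voxel encodings organized into fear-preferring / SCR-preferring /
shared / null regions, single-trial activity patterns, BOLD run time
series, and continuous electrodermal traces.

The rating model is a per-category latent fearfulness plus per-subject
susceptibility, thresholded into 0-5 at quantiles calibrated to a 41%
no-fear trial share.  The SCR model is Bernoulli(respond) x shifted
lognormal amplitude whose drive increases with the trial's rating
(``coupling``) plus a category-specific reactivity component; the respond
intercept is solved numerically so the sub-0.2 uS share hits its target
exactly in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .config import GeneratorConfig, ConfigurationError, ROLE_NAMES
from .lss import TrialBetaMatrix, convolve_onsets, DesignError
from .scr import SCRTrace

# rating latent variance shares (category fearfulness / subject susceptibility)
V_CAT = 0.35
V_SUB = 0.15
# group-level shares of nonzero rating levels 1..5 (very low .. very high),
# renormalized against 1 - fear_zero_target
NONZERO_PROFILE = np.array([0.147, 0.159, 0.128, 0.110, 0.046])

# SCR model constants
SCR_CAT_SD = 0.55    # category-specific reactivity sd on the drive scale
SCR_SUBJ_SD = 0.3    # subject reactivity sd on the drive scale
AMP_LOG_MU = np.log(0.25)
AMP_LOG_SIGMA = 1.0
AMP_DRIVE_GAIN = 0.3
SCR_FLOOR = 0.2

# electrodermal trace shape: Gaussian phasic bump peaking 2.5 s post onset
BUMP_PEAK_TIME = 2.5
BUMP_SD = 0.3
TONIC_LEVEL = 2.0
TRACE_PAD_PRE = 5.0
TRACE_PAD_POST = 8.0

_STREAMS = {
    "design": 1, "ratings": 2, "scr": 3, "parcellation": 4,
    "encoding": 5, "betas": 6, "bold": 7, "trace": 8,
}


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, _STREAMS[stream], extra)))


# ---------------------------------------------------------------------------
# Containers

@dataclass(frozen=True)
class ExperimentDesign:
    """Presentation schedule, identical for every subject (as in the study,
    where the pseudo-randomized sequence was fixed across participants).

    ``schedule`` has one row per presentation: run (1-based), presentation
    (0-based within run), onset (s from run start), category, chunk_size,
    chunk_id (0-based within subject), chunk_first.
    """

    schedule: pd.DataFrame
    subjects: tuple[int, ...]
    tr: float

    @property
    def trials(self) -> pd.DataFrame:
        """Long per-subject trial table (subject column added)."""
        frames = []
        for s in self.subjects:
            f = self.schedule.copy()
            f.insert(0, "subject", s)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    @property
    def chunk_first_trials(self) -> pd.DataFrame:
        return self.schedule[self.schedule["chunk_first"]].reset_index(drop=True)

    @property
    def n_chunk_first(self) -> int:
        return int(self.schedule["chunk_first"].sum())


@dataclass(frozen=True)
class LatentOutcomes:
    """Ground-truth outcomes: ratings (subjects x categories, int 0-5) and
    per chunk-first trial SCR amplitudes in uS (point mass at 0)."""

    ratings: pd.DataFrame
    scr_true: pd.DataFrame  # subject, run, presentation, category, amplitude
    scr_available: dict[int, bool] = field(default_factory=dict)

    def trial_ratings(self, design: ExperimentDesign, subject: int) -> np.ndarray:
        """Rating of each chunk-first trial (offline semantics: constant per
        subject x category)."""
        cats = design.chunk_first_trials["category"].to_numpy()
        return self.ratings.loc[subject].to_numpy()[cats]

    def subject_scr(self, subject: int) -> pd.DataFrame:
        return self.scr_true[self.scr_true["subject"] == subject].reset_index(drop=True)


@dataclass(frozen=True)
class Parcellation:
    """Voxel -> region assignment plus region metadata."""

    voxel_region: np.ndarray  # region id per voxel
    regions: pd.DataFrame  # region, name, hemisphere

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def voxels_of(self, region: int) -> np.ndarray:
        return np.flatnonzero(self.voxel_region == region)


@dataclass(frozen=True)
class VoxelEncoding:
    """Planted per-voxel weights and per-region roles."""

    w_fear: np.ndarray
    w_scr: np.ndarray
    region_role: np.ndarray  # role name per region


# ---------------------------------------------------------------------------
# Generators

def generate_design(config: GeneratorConfig) -> ExperimentDesign:
    """Pseudo-randomized chunked schedule; onsets at one presentation per TR."""
    rng = _rng(config.seed, "design")
    sizes = []
    for size, count in sorted(config.chunk_size_counts.items()):
        sizes += [size] * count
    n_chunks = len(sizes)
    # category list balanced over the run's chunks, then shuffled
    reps = -(-n_chunks // config.n_categories)
    base_cats = np.tile(np.arange(config.n_categories), reps)[:n_chunks]

    rows = []
    chunk_id = 0
    for run in range(1, config.n_runs + 1):
        order = rng.permutation(n_chunks)
        cats = rng.permutation(base_cats)
        pres = 0
        for j, k in enumerate(order):
            for i in range(sizes[k]):
                rows.append(
                    (run, pres, pres * config.tr, int(cats[j]), sizes[k], chunk_id, i == 0)
                )
                pres += 1
            chunk_id += 1
        if pres != config.presentations_per_run:
            raise ConfigurationError("chunk sizes do not tile the run")  # pragma: no cover
    schedule = pd.DataFrame(
        rows,
        columns=["run", "presentation", "onset", "category", "chunk_size",
                 "chunk_id", "chunk_first"],
    )
    return ExperimentDesign(schedule, tuple(range(config.n_subjects)), config.tr)


def _rating_thresholds(fear_zero_target: float) -> np.ndarray:
    """Latent-normal cut points for levels 0..5 from the marginal targets."""
    from scipy.stats import norm

    probs = np.concatenate(
        [[fear_zero_target], (1 - fear_zero_target) * NONZERO_PROFILE / NONZERO_PROFILE.sum()]
    )
    cum = np.cumsum(probs)[:-1]
    return norm.ppf(np.clip(cum, 1e-12, 1 - 1e-12))


def generate_fear_ratings(design: ExperimentDesign, config: GeneratorConfig) -> pd.DataFrame:
    """Ordinal 0-5 rating per subject x category (constant over trials).

    Latent z = sqrt(V_CAT) * category fearfulness + sqrt(V_SUB) * subject
    susceptibility + residual, cut at standard-normal quantiles so the
    marginal no-fear share equals ``fear_zero_target`` and the nonzero
    levels follow the group profile.
    """
    rng = _rng(config.seed, "ratings")
    if config.fear_zero_target >= 1.0:
        z = np.full((config.n_subjects, config.n_categories), -np.inf)
    else:
        cat = rng.standard_normal(config.n_categories)
        sub = rng.standard_normal(config.n_subjects)
        eps = rng.standard_normal((config.n_subjects, config.n_categories))
        z = (
            np.sqrt(V_CAT) * cat[None, :]
            + np.sqrt(V_SUB) * sub[:, None]
            + np.sqrt(1 - V_CAT - V_SUB) * eps
        )
    cuts = _rating_thresholds(config.fear_zero_target)
    ratings = np.digitize(z, cuts)
    frame = pd.DataFrame(
        ratings,
        index=pd.Index(range(config.n_subjects), name="subject"),
        columns=pd.Index(range(config.n_categories), name="category"),
    )
    return frame


def generate_scr_amplitudes(
    design: ExperimentDesign, ratings: pd.DataFrame, config: GeneratorConfig
) -> pd.DataFrame:
    """Zero-inflated SCR amplitude per chunk-first trial, coupled to ratings.

    Trial drive = coupling * z(rating) + category reactivity + subject
    reactivity; respond ~ Bernoulli(expit(a + drive)) with ``a`` solved so
    the expected sub-floor share equals ``scr_zero_target``; responders
    draw 0.2 + lognormal(mu + gain*drive, sigma) uS.
    """
    rng = _rng(config.seed, "scr")
    cat_sd = getattr(config, "scr_category_sd", SCR_CAT_SD)
    cat_react = rng.standard_normal(config.n_categories) * cat_sd
    sub_react = rng.standard_normal(config.n_subjects) * SCR_SUBJ_SD

    firsts = design.chunk_first_trials
    cats = firsts["category"].to_numpy()
    rows = []
    drives = []
    for s in design.subjects:
        r = ratings.loc[s].to_numpy()[cats].astype(float)
        sd = r.std()
        z = (r - r.mean()) / sd if sd > 0 else np.zeros_like(r)
        drives.append(config.coupling * z + cat_react[cats] + sub_react[s])
    drive = np.concatenate(drives)

    target = 1.0 - config.scr_zero_target
    if target <= 0:
        p = np.zeros_like(drive)
    elif target >= 1:
        p = np.ones_like(drive)
    else:
        a = brentq(lambda a: expit(a + drive).mean() - target, -30, 30)
        p = expit(a + drive)
    respond = rng.random(drive.size) < p
    log_amp = rng.normal(AMP_LOG_MU + AMP_DRIVE_GAIN * drive, AMP_LOG_SIGMA)
    amplitude = np.where(respond, SCR_FLOOR + np.exp(log_amp), 0.0)

    i = 0
    n_first = len(firsts)
    for s in design.subjects:
        sub = firsts[["run", "presentation", "category"]].copy()
        sub.insert(0, "subject", s)
        sub["amplitude"] = amplitude[i : i + n_first]
        rows.append(sub)
        i += n_first
    return pd.concat(rows, ignore_index=True)


def generate_outcomes(design: ExperimentDesign, config: GeneratorConfig) -> LatentOutcomes:
    """Ratings + SCR amplitudes + per-subject SCR availability flags."""
    ratings = generate_fear_ratings(design, config)
    scr_true = generate_scr_amplitudes(design, ratings, config)
    rng = _rng(config.seed, "scr", extra=1)
    missing = set(rng.choice(config.n_subjects, size=config.scr_missing, replace=False))
    available = {int(s): s not in missing for s in design.subjects}
    return LatentOutcomes(ratings, scr_true, available)


def generate_parcellation(config: GeneratorConfig) -> Parcellation:
    """Contiguous voxel blocks, near-equal sizes (remainder to the earliest
    regions), alternating hemisphere labels."""
    if config.n_regions > config.n_voxels:
        raise ConfigurationError("n_regions may not exceed n_voxels")
    voxel_region = np.empty(config.n_voxels, dtype=int)
    for rid, block in enumerate(np.array_split(np.arange(config.n_voxels), config.n_regions)):
        voxel_region[block] = rid
    regions = pd.DataFrame(
        {
            "region": np.arange(config.n_regions),
            "name": [f"region_{i:03d}" for i in range(config.n_regions)],
            "hemisphere": ["L" if i % 2 == 0 else "R" for i in range(config.n_regions)],
        }
    )
    return Parcellation(voxel_region, regions)


def generate_encoding(config: GeneratorConfig, parcellation: Parcellation) -> VoxelEncoding:
    """Assign region roles (exact largest-remainder counts, shuffled) and draw
    Gaussian weights scaled by the effect sizes; role-zero constraints exact."""
    rng = _rng(config.seed, "encoding")
    n = parcellation.n_regions
    fracs = np.array([config.region_role_fractions.get(r, 0.0) for r in ROLE_NAMES])
    counts = np.floor(fracs * n).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(fracs * n - counts))
    for k in order[:rem]:
        counts[k] += 1
    roles = np.repeat(np.array(ROLE_NAMES, dtype=object), counts)
    roles = roles[rng.permutation(n)]

    role_per_voxel = roles[parcellation.voxel_region]
    fear_mask = np.isin(role_per_voxel, ("fear_only", "both"))
    scr_mask = np.isin(role_per_voxel, ("scr_only", "both"))
    w_fear = np.where(fear_mask, rng.normal(0, 1, config.n_voxels), 0.0) * config.effect_size_fear
    w_scr = np.where(scr_mask, rng.normal(0, 1, config.n_voxels), 0.0) * config.effect_size_scr
    return VoxelEncoding(w_fear, w_scr, roles)


def signal_matrix(
    design: ExperimentDesign,
    outcomes: LatentOutcomes,
    encoding: VoxelEncoding,
    subject: int,
) -> np.ndarray:
    """Noise-free activity per chunk-first trial:
    w_fear * rating + w_scr * sqrt(amplitude)."""
    r = outcomes.trial_ratings(design, subject).astype(float)
    amp = outcomes.subject_scr(subject)["amplitude"].to_numpy()
    return np.outer(r, encoding.w_fear) + np.outer(np.sqrt(amp), encoding.w_scr)


def generate_trial_betas(
    design: ExperimentDesign,
    outcomes: LatentOutcomes,
    encoding: VoxelEncoding,
    config: GeneratorConfig,
    subject: int,
) -> TrialBetaMatrix:
    """Per-subject trials x voxels activity estimates (chunk-first only)."""
    rng = _rng(config.seed, "betas", extra=subject)
    signal = signal_matrix(design, outcomes, encoding, subject)
    betas = signal + rng.normal(0, config.noise_sd, signal.shape) if config.noise_sd > 0 else signal
    info = design.chunk_first_trials[["run", "presentation", "onset", "category"]].copy()
    return TrialBetaMatrix(subject, betas, info)


def expand_chunk_amplitudes(schedule: pd.DataFrame, chunk_first_amplitudes: np.ndarray) -> np.ndarray:
    """Per-presentation amplitudes: every presentation inherits its chunk's
    (chunk-first) amplitude.  Accepts (n_first,) or (n_first, n_voxels)."""
    amps = np.asarray(chunk_first_amplitudes, dtype=float)
    firsts = schedule[schedule["chunk_first"]]
    if len(firsts) != amps.shape[0]:
        raise ValueError(
            f"{amps.shape[0]} amplitudes for {len(firsts)} chunk-first trials"
        )
    chunk_ids = firsts["chunk_id"].to_numpy()
    lookup = {int(c): i for i, c in enumerate(chunk_ids)}
    idx = np.array([lookup[int(c)] for c in schedule["chunk_id"]])
    return amps[idx]


def generate_bold(
    design: ExperimentDesign,
    presentation_amplitudes: np.ndarray,
    config: GeneratorConfig,
    noise_sd: float = 0.0,
    drift: float = 0.0,
    seed_extra: int = 0,
) -> dict[int, np.ndarray]:
    """Run time series: sum of HRF-convolved sticks at each presentation
    onset, plus optional linear drift (units per scan) and Gaussian noise.

    ``presentation_amplitudes`` has one row per presentation of the
    schedule ((n_presentations,) or (n_presentations, n_voxels)); use
    :func:`expand_chunk_amplitudes` to spread chunk-first amplitudes.
    Returns {run: scans x voxels}.
    """
    rng = _rng(config.seed, "bold", extra=seed_extra)
    amps = np.asarray(presentation_amplitudes, dtype=float)
    if amps.ndim == 1:
        amps = amps[:, None]
    if amps.shape[0] != len(design.schedule):
        raise ValueError("need one amplitude row per presentation")
    n_scans = config.presentations_per_run + int(np.ceil(32.0 / config.tr))
    out: dict[int, np.ndarray] = {}
    for run, run_trials in design.schedule.groupby("run"):
        onsets = run_trials["onset"].to_numpy()
        if onsets.max() >= n_scans * config.tr:
            raise DesignError("onsets beyond scan duration")
        a = amps[run_trials.index.to_numpy()]
        series = np.empty((n_scans, a.shape[1]))
        for v in range(a.shape[1]):
            series[:, v] = convolve_onsets(onsets, a[:, v], n_scans, config.tr)
        if drift:
            series += drift * np.arange(n_scans)[:, None]
        if noise_sd:
            series += rng.normal(0, noise_sd, series.shape)
        out[int(run)] = series
    return out


def generate_scr_trace(
    design: ExperimentDesign,
    subject_scr: pd.DataFrame,
    config: GeneratorConfig,
    noise_sd: float = 0.0,
    baseline: float = TONIC_LEVEL,
    seed_extra: int = 0,
) -> dict[int, SCRTrace]:
    """Continuous electrodermal trace per run.

    Tonic baseline plus a Gaussian phasic bump per chunk-first trial,
    peaking ``BUMP_PEAK_TIME`` s after onset (inside the 1-5 s scoring
    window) with peak height equal to the planted amplitude.  The trace
    starts before the run so the first trial has a full baseline window.
    """
    rng = _rng(config.seed, "trace", extra=seed_extra)
    run_dur = config.presentations_per_run * config.tr
    out: dict[int, SCRTrace] = {}
    for run, run_trials in design.schedule.groupby("run"):
        firsts = run_trials[run_trials["chunk_first"]]
        amp_rows = subject_scr[subject_scr["run"] == run]
        amp = dict(zip(amp_rows["presentation"], amp_rows["amplitude"]))
        n = int(round((run_dur + TRACE_PAD_PRE + TRACE_PAD_POST) * config.scr_rate)) + 1
        t = -TRACE_PAD_PRE + np.arange(n) / config.scr_rate
        samples = np.full(n, float(baseline))
        for _, trial in firsts.iterrows():
            a = amp.get(int(trial["presentation"]), 0.0)
            if a:
                dtc = t - float(trial["onset"]) - BUMP_PEAK_TIME
                samples += a * np.exp(-(dtc**2) / (2 * BUMP_SD**2))
        if noise_sd:
            samples += rng.normal(0, noise_sd, n)
        out[int(run)] = SCRTrace(samples, config.scr_rate, start=-TRACE_PAD_PRE)
    return out


# ---------------------------------------------------------------------------
# Cohort convenience

@dataclass
class SyntheticCohort:
    """Everything the analysis pipeline consumes, for one generated cohort."""

    config: GeneratorConfig
    design: ExperimentDesign
    outcomes: LatentOutcomes
    parcellation: Parcellation
    encoding: VoxelEncoding
    betas: dict[int, TrialBetaMatrix]

    def scr_table(self, subject: int) -> pd.DataFrame:
        """Planted per-trial SCR table on the scoring module's schema
        (raw / thresholded / sqrt-transformed amplitudes)."""
        sub = self.outcomes.subject_scr(subject)
        amp = sub["amplitude"].to_numpy()
        thresholded = np.where(amp < SCR_FLOOR, 0.0, amp)
        table = sub.rename(columns={"amplitude": "raw"}).copy()
        table["thresholded"] = thresholded
        table["transformed"] = np.sqrt(thresholded)
        onset = self.design.chunk_first_trials["onset"].to_numpy()
        table["onset"] = onset
        return table.drop(columns=["subject"])

    @property
    def scr_subjects(self) -> list[int]:
        return [s for s in self.design.subjects if self.outcomes.scr_available[s]]


def simulate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a full cohort: design, outcomes, parcellation, encoding, betas."""
    design = generate_design(config)
    outcomes = generate_outcomes(design, config)
    parcellation = generate_parcellation(config)
    encoding = generate_encoding(config, parcellation)
    betas = {
        s: generate_trial_betas(design, outcomes, encoding, config, s)
        for s in design.subjects
    }
    return SyntheticCohort(config, design, outcomes, parcellation, encoding, betas)
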