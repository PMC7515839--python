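"""Configuration objects for the synthetic cohort generator and the pipeline.

The generator defaults encode the study conditions the analysis assumes:
six runs of 600 image presentations in chunks of 2/3/4/6 images of the same
animal category (one presentation per TR of 2 s), 30 categories, offline
fear ratings on a 0-5 scale with ~41% no-fear trials, and zero-inflated
skin-conductance amplitudes with ~72% of trials below the 0.2 uS scoring
floor, coupled to the ratings so the group category-level correlation sits
near 0.43.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields as dc_fields
from pathlib import Path
from typing import Any, Mapping

import yaml

ROLE_NAMES = ("fear_only", "scr_only", "both", "null")


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Attributes
    ----------
    n_subjects:
        Size of the simulated discovery cohort.
    n_runs, presentations_per_run:
        Scanning schedule; every presentation occupies one TR.
    chunk_size_counts:
        Number of chunks of each size per run.  The sizes times counts must
        sum to ``presentations_per_run``.  The default {2:12, 3:12, 4:18,
        6:78} yields 120 chunks per run and hence 720 chunk-first trials
        per subject over six runs.
    n_categories:
        Animal categories; each chunk shows images of a single category.
    n_voxels, n_regions:
        Size of the synthetic brain and its parcellation.
    region_role_fractions:
        Fractions of regions whose voxels encode only fear, only SCR,
        both, or nothing.
    effect_size_fear, effect_size_scr:
        Standard deviation of the planted per-voxel encoding weights.
    noise_sd:
        Gaussian noise added to each single-trial beta.
    fear_zero_target:
        Target marginal share of no-fear (rating 0) trials.
    scr_zero_target:
        Target share of trials with SCR amplitude below the 0.2 uS floor.
    coupling:
        Strength of the rating -> SCR link on the latent drive scale.
    scr_category_sd:
        Spread of the category-specific SCR reactivity (shared across
        subjects, independent of the fear latent) on the drive scale; set
        to 0 for a strict rating/SCR independence null.
    tr:
        Repetition time in seconds (also the stimulus onset asynchrony).
    scr_rate:
        Sampling rate of the synthetic electrodermal trace, in Hz.
    scr_missing:
        Number of subjects whose electrodermal recording is unavailable
        (they are kept for fear decoding only).
    """

    n_subjects: int = 20
    n_runs: int = 6
    presentations_per_run: int = 600
    chunk_size_counts: Mapping[int, int] = field(
        default_factory=lambda: {2: 12, 3: 12, 4: 18, 6: 78}
    )
    n_categories: int = 30
    n_voxels: int = 2000
    n_regions: int = 40
    region_role_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "fear_only": 0.2,
            "scr_only": 0.2,
            "both": 0.1,
            "null": 0.5,
        }
    )
    effect_size_fear: float = 1.0
    effect_size_scr: float = 1.0
    noise_sd: float = 3.0
    scr_zero_target: float = 0.7179
    fear_zero_target: float = 0.41
    coupling: float = 0.45
    scr_category_sd: float = 0.55
    tr: float = 2.0
    scr_rate: float = 10.0
    scr_missing: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_subjects": self.n_subjects,
            "n_runs": self.n_runs,
            "presentations_per_run": self.presentations_per_run,
            "n_categories": self.n_categories,
            "n_voxels": self.n_voxels,
            "n_regions": self.n_regions,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        if not self.chunk_size_counts:
            raise ConfigurationError("chunk_size_counts must not be empty")
        for size, count in self.chunk_size_counts.items():
            if size < 1 or count < 1:
                raise ConfigurationError(
                    f"chunk sizes and counts must be >= 1, got {size}:{count}"
                )
        total = sum(s * c for s, c in self.chunk_size_counts.items())
        if total != self.presentations_per_run:
            raise ConfigurationError(
                "chunk_size_counts inconsistent with presentations_per_run: "
                f"sum(size*count) = {total} != {self.presentations_per_run}"
            )
        if set(self.region_role_fractions) - set(ROLE_NAMES):
            raise ConfigurationError(
                f"unknown region roles: {set(self.region_role_fractions) - set(ROLE_NAMES)}"
            )
        fracs = [self.region_role_fractions.get(r, 0.0) for r in ROLE_NAMES]
        if any(f < 0 or f > 1 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"region_role_fractions must lie in [0,1] and sum to 1, got {fracs}"
            )
        for name in ("scr_zero_target", "fear_zero_target"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0,1], got {v}")
        if self.n_regions > self.n_voxels:
            raise ConfigurationError("n_regions may not exceed n_voxels")
        if self.scr_category_sd < 0:
            raise ConfigurationError("scr_category_sd must be >= 0")
        if self.tr <= 0 or self.scr_rate <= 0:
            raise ConfigurationError("tr and scr_rate must be positive")
        if not 0 <= self.scr_missing <= self.n_subjects:
            raise ConfigurationError("scr_missing must lie in [0, n_subjects]")

    @property
    def chunks_per_run(self) -> int:
        return sum(self.chunk_size_counts.values())

    @property
    def n_chunk_first(self) -> int:
        """Chunk-first trials per subject (720 at defaults)."""
        return self.chunks_per_run * self.n_runs

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["chunk_size_counts"] = {int(k): int(v) for k, v in self.chunk_size_counts.items()}
        return d


@dataclass(frozen=True)
class DecoderConfig:
    """Support-vector-regression hyperparameters and evaluation settings."""

    C: float = 1.0
    epsilon: float = 0.1
    scale_features: bool = True
    n_perm: int = 1000

    def __post_init__(self) -> None:
        if self.C <= 0 or self.epsilon < 0:
            raise ConfigurationError("C must be > 0 and epsilon >= 0")
        if self.n_perm < 1:
            raise ConfigurationError("n_perm must be >= 1")


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline configuration."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    fdr_q: float = 0.05
    run_regions: bool = True
    run_scr: bool = True
    run_single_trial: bool = False
    run_validation_cohort: bool = False
    n_validation_subjects: int = 12
    out_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.fdr_q < 1:
            raise ConfigurationError("fdr_q must lie in (0,1)")
        if self.n_validation_subjects < 1:
            raise ConfigurationError("n_validation_subjects must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["generator"] = self.generator.to_dict()
        return d


def _build(cls, data: Mapping[str, Any], context: str):
    known = {f.name for f in dc_fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown key(s) in {context}: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML (or JSON) file.

    An empty file yields all defaults; unknown keys are rejected with the
    offending key named in the error.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(data).__name__}")
    data = dict(data)
    gen = data.pop("generator", {})
    dec = data.pop("decoder", {})
    if "chunk_size_counts" in gen:
        gen["chunk_size_counts"] = {int(k): int(v) for k, v in gen["chunk_size_counts"].items()}
    generator = _build(GeneratorConfig, gen, "generator")
    decoder = _build(DecoderConfig, dec, "decoder")
    cfg = _build(PipelineConfig, data, "pipeline")
    return PipelineConfig(
        **{**{f.name: getattr(cfg, f.name) for f in dc_fields(PipelineConfig)},
           "generator": generator, "decoder": decoder}
    )


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    """Write a pipeline configuration as YAML (round-trips via load_config)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
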