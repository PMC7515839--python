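"""Shared fixtures: synthetic cohorts at several sizes.

Everything is generated at test time from seeded configurations; no data
files are stored.
"""

from __future__ import annotations

import numpy as np
import pytest

from feardecode.binning import build_binned_dataset
from feardecode.config import DecoderConfig, GeneratorConfig
from feardecode.pipeline import fear_labels, scr_labels
from feardecode.synth import simulate_cohort


def tiny_generator_config(**overrides) -> GeneratorConfig:
    """A minimal but structurally complete design (2 runs x 30 presentations)."""
    base = dict(
        n_subjects=4,
        n_runs=2,
        presentations_per_run=30,
        chunk_size_counts={2: 3, 3: 2, 4: 3, 6: 1},
        n_categories=5,
        n_voxels=30,
        n_regions=5,
        noise_sd=1.0,
        seed=0,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def tiny_config() -> GeneratorConfig:
    return tiny_generator_config()


@pytest.fixture(scope="session")
def small_cohort():
    """A mid-sized cohort with the full-size trial schedule: 8 subjects,
    400 voxels, 10 regions, default 6x600 design."""
    cfg = GeneratorConfig(seed=21, n_subjects=8, n_voxels=400, n_regions=10)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_binned(small_cohort):
    fear = build_binned_dataset(small_cohort.betas, fear_labels(small_cohort), "fear")
    scr = build_binned_dataset(
        small_cohort.betas, scr_labels(small_cohort), "scr",
        rng=np.random.default_rng(5),
    )
    return {"fear": fear, "scr": scr}


@pytest.fixture(scope="session")
def decoder_config() -> DecoderConfig:
    return DecoderConfig(n_perm=100)


@pytest.fixture(scope="session")
def default_cohort():
    """The study-condition cohort used by the acceptance checks: 20
    subjects, 2000 voxels, 40 regions at the default role fractions."""
    return simulate_cohort(GeneratorConfig(seed=7))
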