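"""End-to-end orchestration: simulate -> score -> bin -> decode -> regions.

A single global seed deterministically derives every stage's random stream
(generator, SCR level-0 subsampling, permutation tests, validation
cohort), so re-running with the same configuration reproduces all outputs
bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .binning import build_binned_dataset, categorical_means
from .config import PipelineConfig
from .decoding import (
    apply_to_cohort,
    cross_decode,
    evaluate_single_trial,
    loso_cv,
    predict_categorical,
    train_decoder,
)
from .regions import conjunction, preference_table, region_loso_decode
from .scr import _zscore, category_means, group_category_vector, group_level_correlation
from .synth import SyntheticCohort, simulate_cohort

logger = logging.getLogger(__name__)

_STAGE_SEEDS = {"scr_bins": 11, "perm_fear": 12, "perm_scr": 13, "perm_cross": 14,
                "regions": 15, "validation": 16, "perm_cohort": 17}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, _STAGE_SEEDS[stage])))


def fear_labels(cohort: SyntheticCohort) -> dict[int, np.ndarray]:
    """Per-trial fear rating per subject (offline rating of the category)."""
    return {
        s: cohort.outcomes.trial_ratings(cohort.design, s)
        for s in cohort.design.subjects
    }


def scr_labels(cohort: SyntheticCohort) -> dict[int, np.ndarray]:
    """Per-trial sqrt-transformed SCR per subject with an available trace."""
    return {s: cohort.scr_table(s)["transformed"].to_numpy() for s in cohort.scr_subjects}


def group_fear_vector(cohort: SyntheticCohort) -> pd.Series:
    """Group-level standardized category means of the fear ratings."""
    per_subject = cohort.outcomes.ratings.apply(
        lambda row: pd.Series(_zscore(row.to_numpy(dtype=float), "subject ratings"),
                              index=row.index),
        axis=1,
    )
    vec = _zscore(per_subject.mean(axis=0).to_numpy(), "group fear categories")
    return pd.Series(vec, index=per_subject.columns)


def group_scr_vector(cohort: SyntheticCohort) -> pd.Series:
    """Group-level standardized category means of the SCR (Fig-2 procedure)."""
    tables = {s: cohort.scr_table(s) for s in cohort.scr_subjects}
    per_subject = category_means(tables)
    return pd.Series(group_category_vector(per_subject), index=per_subject.columns)


def rating_scr_correlation(cohort: SyntheticCohort) -> dict[str, float]:
    """Group category-level correlation between fear ratings and SCR."""
    fear = group_fear_vector(cohort)
    scrv = group_scr_vector(cohort)
    return group_level_correlation(fear.to_numpy(), scrv.reindex(fear.index).to_numpy())


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; return the summary.

    When ``config.out_dir`` is set, per-stage artifacts (events, ratings,
    region table, summary JSON) are written there.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    seed = config.seed
    gen_cfg = replace(config.generator, seed=seed)
    logger.info("simulating cohort: %d subjects, %d voxels, %d regions",
                gen_cfg.n_subjects, gen_cfg.n_voxels, gen_cfg.n_regions)
    cohort = simulate_cohort(gen_cfg)

    summary: dict = {
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16],
        "n_chunk_first": cohort.design.n_chunk_first,
    }

    # --- outcome coupling (Fig-2 style group correlation) -----------------
    if config.run_scr:
        summary["rating_scr_correlation"] = rating_scr_correlation(cohort)

    # --- binning ----------------------------------------------------------
    flabels = fear_labels(cohort)
    fear_ds = build_binned_dataset(cohort.betas, flabels, "fear")
    datasets = {"fear": fear_ds}
    if config.run_scr:
        scr_ds = build_binned_dataset(
            {s: cohort.betas[s] for s in cohort.scr_subjects},
            scr_labels(cohort), "scr", rng=_stage_rng(seed, "scr_bins"),
        )
        datasets["scr"] = scr_ds
    logger.info("binned datasets: %s",
                {k: f"{len(v.subjects)} subjects" for k, v in datasets.items()})

    # --- whole-brain decoding --------------------------------------------
    n_perm = config.decoder.n_perm
    results = {}
    results["fear"] = loso_cv(fear_ds, config.decoder, n_perm, _stage_rng(seed, "perm_fear"))
    summary["fear_auc"] = results["fear"].auc
    summary["fear_p"] = results["fear"].p
    summary["fear_critical"] = results["fear"].critical_value
    if config.run_scr:
        results["scr"] = loso_cv(scr_ds, config.decoder, n_perm, _stage_rng(seed, "perm_scr"))
        summary["scr_auc"] = results["scr"].auc
        summary["scr_p"] = results["scr"].p
        summary["scr_critical"] = results["scr"].critical_value

        rng_cross = _stage_rng(seed, "perm_cross")
        cross_fs = cross_decode(results["fear"].fold_decoders, scr_ds, n_perm, rng_cross)
        cross_sf = cross_decode(results["scr"].fold_decoders, fear_ds, n_perm, rng_cross)
        summary["cross_aucs"] = {
            "fear_decoder_on_scr": cross_fs.auc,
            "scr_decoder_on_fear": cross_sf.auc,
            "fear_decoder_on_scr_p": cross_fs.p,
            "scr_decoder_on_fear_p": cross_sf.p,
        }

    # --- categorical prediction ------------------------------------------
    cat_images = {
        s: categorical_means(cohort.betas[s], gen_cfg.n_categories)
        for s in cohort.design.subjects
    }
    summary["categorical_r"] = {
        "fear": predict_categorical(
            results["fear"].fold_decoders, cat_images, group_fear_vector(cohort)
        )
    }
    if config.run_scr:
        summary["categorical_r"]["scr"] = predict_categorical(
            results["scr"].fold_decoders,
            {s: cat_images[s] for s in scr_ds.subjects},
            group_scr_vector(cohort),
        )

    # --- single-trial evaluation (optional) ------------------------------
    if config.run_single_trial:
        trial_images = {s: cohort.betas[s].betas for s in cohort.design.subjects}
        summary["single_trial_auc"] = {
            "fear": evaluate_single_trial(
                results["fear"].fold_decoders, trial_images, flabels
            ).auc
        }

    # --- held-out validation cohort (optional) ---------------------------
    if config.run_validation_cohort:
        val_cfg = replace(
            gen_cfg,
            n_subjects=config.n_validation_subjects,
            seed=int(_stage_rng(seed, "validation").integers(2**31 - 1)),
        )
        val_cohort = simulate_cohort(val_cfg)
        val_ds = build_binned_dataset(val_cohort.betas, fear_labels(val_cohort), "fear")
        X, y, _ = fear_ds.stacked()
        frozen = train_decoder(X, y, "fear", tuple(fear_ds.subjects), config.decoder)
        res = apply_to_cohort(frozen, val_ds, n_perm, _stage_rng(seed, "perm_cohort"))
        summary["validation_fear_auc"] = res.auc
        summary["validation_fear_p"] = res.p

    # --- within-region comparison ----------------------------------------
    region_table = None
    if config.run_regions and config.run_scr:
        logger.info("within-region decoding over %d regions", cohort.parcellation.n_regions)
        region_res = region_loso_decode(
            fear_ds, scr_ds, cohort.parcellation, config.decoder,
            n_perm=min(200, n_perm), rng=_stage_rng(seed, "regions"),
        )
        region_table = preference_table(region_res, q=config.fdr_q)
        conj = conjunction(region_res)
        region_table = region_table.merge(conj[["region", "conjunction"]], on="region")
        summary["region_table"] = region_table.drop(
            columns=["critical_fear", "critical_scr"]
        ).to_dict(orient="records")
        summary["n_regions_fear_preferring"] = int((region_table["preference"] == "fear").sum())
        summary["n_regions_scr_preferring"] = int((region_table["preference"] == "scr").sum())
        summary["n_regions_conjunction"] = int(region_table["conjunction"].sum())

    if config.out_dir:
        _write_artifacts(config, cohort, summary, region_table)
    return summary


def _write_artifacts(config, cohort, summary, region_table) -> None:
    from . import io as fio

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fio.write_events_tsv(cohort.design, out / "events.tsv")
    fio.write_ratings_csv(cohort.outcomes.ratings, out / "ratings.csv")
    cohort.outcomes.scr_true.to_csv(out / "scr_amplitudes.csv", index=False)
    if region_table is not None:
        region_table.to_csv(out / "region_table.tsv", sep="\t", index=False)
    fio.write_summary_json(summary, out / "summary.json")
    logger.info("artifacts written to %s", out)
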