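#!/usr/bin/env python
"""Validate the least-squares-separate single-trial estimator.

Builds noiseless synthetic BOLD for one subject (6 runs, 720 chunk-first
trials, 200 voxels) and measures how well the per-trial LSS betas recover
the planted amplitudes, under three input regimes:

1. responses at the modeled (chunk-first) events only — the machinery
   round trip, where the estimator's model class matches the data up to
   the pooled-nuisance approximation;
2. repeat presentations carrying their chunk's full amplitude — a
   robustness probe of the pooled two-regressor nuisance under repeat
   responses the model cannot fully absorb;
3. a widely spaced design with within-run-constant amplitudes, where
   ordinary least squares is exact.

Writes lss_validation.json under results/.
"""

import argparse
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from feardecode.config import GeneratorConfig
from feardecode.lss import convolve_onsets, estimate_all_betas
from feardecode.synth import (
    expand_chunk_amplitudes,
    generate_bold,
    simulate_cohort,
    signal_matrix,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = GeneratorConfig(seed=args.seed, n_voxels=200, n_regions=20, noise_sd=0.0)
    cohort = simulate_cohort(cfg)
    design = cohort.design
    planted = signal_matrix(design, cohort.outcomes, cohort.encoding, 0)
    first_mask = design.schedule["chunk_first"].to_numpy()

    # regime 1: event-only responses
    per_pres = np.zeros((len(design.schedule), cfg.n_voxels))
    per_pres[first_mask] = planted
    bold = generate_bold(design, per_pres, cfg, drift=0.02)
    betas = estimate_all_betas(bold, design.schedule, cfg.tr)
    r_events = float(np.corrcoef(betas.betas.ravel(), planted.ravel())[0, 1])

    # regime 2: repeats inherit the chunk amplitude
    per_pres_rep = expand_chunk_amplitudes(design.schedule, planted)
    bold_rep = generate_bold(design, per_pres_rep, cfg, drift=0.02)
    betas_rep = estimate_all_betas(bold_rep, design.schedule, cfg.tr)
    r_repeats = float(np.corrcoef(betas_rep.betas.ravel(), planted.ravel())[0, 1])

    # regime 3: non-overlapping design, within-run-constant amplitudes
    onsets = np.arange(6) * 40.0
    trials = pd.DataFrame(
        {"run": 1, "presentation": np.arange(6), "onset": onsets, "chunk_first": True,
         "category": 0, "chunk_id": np.arange(6), "chunk_size": 1}
    )
    amps = np.array([0.5, 1.0, 2.0])
    y = sum(np.outer(convolve_onsets([o], [1.0], 130, cfg.tr), amps) for o in onsets)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rec = estimate_all_betas({1: y}, trials, cfg.tr)
    max_err = float(np.abs(rec.betas - np.tile(amps, (6, 1))).max())

    out = {
        "r_event_only_responses": round(r_events, 5),
        "r_repeats_at_chunk_amplitude": round(r_repeats, 5),
        "nonoverlap_max_abs_error": max_err,
        "n_trials": int(betas.n_trials),
        "n_voxels": cfg.n_voxels,
        "seed": args.seed,
    }
    args.out_dir.mkdir(parents=True, exist_ok=True)
    with open(args.out_dir / "lss_validation.json", "w") as fh:
        json.dump(out, fh, indent=2)

    print(f"event-only round trip:      r = {r_events:.4f} over {planted.size} trial-voxel pairs")
    print(f"repeats at chunk amplitude: r = {r_repeats:.4f} "
          "(pooled nuisance cannot absorb per-chunk repeat amplitudes at 2 s SOA)")
    print(f"non-overlapping design:     max |error| = {max_err:.2e}")


if __name__ == "__main__":
    main()
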