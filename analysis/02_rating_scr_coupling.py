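#!/usr/bin/env python
"""Group-level coupling between subjective fear ratings and skin-conductance
reactivity.

Reproduces the category-level correlation procedure on the synthetic
cohort: per subject, drop the first chunk-first trial of each run,
winsorize the sqrt-transformed reactivities at the 5th/95th percentile,
average within animal category and z-score; average the standardized
category means across subjects, z-score at the group level, and correlate
with the identically processed fear ratings (Pearson, df = categories-2,
Fisher-z CI).

Writes rating_scr_correlation.json and the paired category means as
category_means.csv under results/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from feardecode.config import GeneratorConfig
from feardecode.pipeline import group_fear_vector, group_scr_vector, rating_scr_correlation
from feardecode.synth import simulate_cohort


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = simulate_cohort(GeneratorConfig(seed=args.seed, n_voxels=40, n_regions=4))
    res = rating_scr_correlation(cohort)
    fear = group_fear_vector(cohort)
    scr = group_scr_vector(cohort)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"category": fear.index, "fear_z": fear.to_numpy(),
                  "scr_z": scr.reindex(fear.index).to_numpy()}).to_csv(
        args.out_dir / "category_means.csv", index=False)
    with open(args.out_dir / "rating_scr_correlation.json", "w") as fh:
        json.dump(res, fh, indent=2)

    print(f"r({res['df']}) = {res['r']:.2f}; P = {res['p']:.3g}; "
          f"95% CI: {res['ci_low']:.2f}-{res['ci_high']:.2f}; R^2 = {res['r2']:.2f}")
    print("category-level reactivity tracks the rated fearfulness of the animal"
          " categories, with substantial unshared variance on both sides")


if __name__ == "__main__":
    main()
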