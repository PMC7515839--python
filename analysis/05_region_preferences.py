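#!/usr/bin/env python
"""Region-by-region comparison of the fear and SCR decoders.

Repeats the LOSO decoding with features restricted to each of the 40
parcellation regions, compares the two prediction correlations per region
with the Fisher r-to-z difference, controls the FDR of the dependent
family with Benjamini-Yekutieli, and reports the AUC-difference preference
map, the conjunction of jointly decodable regions, and how well the
procedure recovers the planted region roles.

Writes region_table.tsv and region_summary.json under results/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from feardecode.binning import build_binned_dataset
from feardecode.config import DecoderConfig, GeneratorConfig
from feardecode.pipeline import fear_labels, scr_labels
from feardecode.regions import conjunction, preference_table, region_loso_decode
from feardecode.synth import simulate_cohort


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--fdr-q", type=float, default=0.05)
    args = ap.parse_args()

    cfg = GeneratorConfig(seed=args.seed)
    cohort = simulate_cohort(cfg)
    rng = np.random.default_rng(np.random.SeedSequence((args.seed, 51)))
    fear_ds = build_binned_dataset(cohort.betas, fear_labels(cohort), "fear")
    scr_ds = build_binned_dataset(cohort.betas, scr_labels(cohort), "scr", rng=rng)

    results = region_loso_decode(
        fear_ds, scr_ds, cohort.parcellation, DecoderConfig(), n_perm=200, rng=rng
    )
    table = preference_table(results, q=args.fdr_q)
    conj = conjunction(results)
    table = table.merge(conj[["region", "conjunction"]], on="region")
    table["planted_role"] = cohort.encoding.region_role[table["region"].to_numpy()]

    roles = table.set_index("region")["planted_role"]
    pref = table.set_index("region")["preference"]
    fear_ids = roles[roles == "fear_only"].index
    scr_ids = roles[roles == "scr_only"].index
    both_ids = roles[roles == "both"].index
    summary = {
        "n_regions": len(table),
        "fear_only_recovered_pct": round(100 * (pref.loc[fear_ids] == "fear").mean(), 1),
        "scr_only_recovered_pct": round(100 * (pref.loc[scr_ids] == "scr").mean(), 1),
        "directional_mislabels": int((pref.loc[fear_ids] == "scr").sum()
                                     + (pref.loc[scr_ids] == "fear").sum()),
        "conjunction_recovered_pct": round(
            100 * table.set_index("region").loc[both_ids, "conjunction"].mean(), 1),
        "n_significant": int((pref != "none").sum()),
        "fdr_q": args.fdr_q,
        "seed": args.seed,
    }

    args.out_dir.mkdir(parents=True, exist_ok=True)
    cols = ["region", "name", "hemisphere", "planted_role", "r_fear", "n_fear",
            "r_scr", "n_scr", "Z", "p", "q", "delta_auc", "preference", "conjunction"]
    table[cols].to_csv(args.out_dir / "region_table.tsv", sep="\t", index=False)
    with open(args.out_dir / "region_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    print(f"{summary['n_significant']}/{len(table)} regions show a significant "
          f"decoder difference at q < {args.fdr_q} (Benjamini-Yekutieli)")
    print(f"planted fear-preferring regions recovered: {summary['fear_only_recovered_pct']}%")
    print(f"planted SCR-preferring regions recovered:  {summary['scr_only_recovered_pct']}%")
    print(f"directional mislabels: {summary['directional_mislabels']}")
    print(f"jointly decodable ('both') regions flagged by the conjunction: "
          f"{summary['conjunction_recovered_pct']}%")
    print(f"full table written to {args.out_dir / 'region_table.tsv'}")


if __name__ == "__main__":
    main()
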