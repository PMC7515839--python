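"""Within-region decoders and the fear-vs-SCR preference comparison.

The LOSO decoding pipeline is repeated with features restricted to each
parcellation region, for both outcomes.  Each region yields a correlation
between pooled predictions and true levels per outcome; the two
correlations are compared with the Fisher r-to-z difference
Z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), the family of
dependent tests is FDR-controlled with the Benjamini-Yekutieli step-up,
and the AUC difference (fear - SCR) gives the preference map.  A
conjunction flags regions whose AUCs exceed their own permutation critical
value for both outcomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .binning import BinnedDataset
from .config import DecoderConfig
from .decoding import DecodingError, loso_cv
from .synth import Parcellation

logger = logging.getLogger(__name__)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher r-to-z comparison of two independent correlations.

    Z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); two-sided p
    from the standard normal.  Antisymmetric under swapping the samples.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1:
            raise ValueError(f"|r| = {abs(r)} >= 1: Fisher transform is infinite")
        if n <= 3:
            raise ValueError(f"need n > 3 per sample, got {n}")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def by_fdr(pvalues: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Yekutieli step-up FDR control (valid under dependence).

    Rejects p(i) <= i*q / (m*c(m)) with c(m) = sum_{i<=m} 1/i for the
    largest such rank and all smaller ones.  Returns (reject mask,
    adjusted q-values).  Backed by statsmodels' ``fdr_by``.
    """
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("p-values must lie in [0,1]")
    reject, qvals, _, _ = multipletests(pvalues, alpha=q, method="fdr_by")
    return reject, qvals


@dataclass
class RegionResults:
    """Per-region LOSO decoding summaries for both outcomes."""

    table: pd.DataFrame  # region, r/n/auc/critical per outcome
    predictions: dict[str, dict[int, pd.DataFrame]]


def _pooled_r(predictions: pd.DataFrame) -> tuple[float, int]:
    pred = predictions["prediction"].to_numpy()
    lev = predictions["level"].to_numpy(dtype=float)
    n = pred.size
    if np.std(pred) == 0 or np.std(lev) == 0:
        return 0.0, n
    return float(stats.pearsonr(pred, lev)[0]), n


def region_loso_decode(
    fear_dataset: BinnedDataset,
    scr_dataset: BinnedDataset,
    parcellation: Parcellation,
    config: DecoderConfig = DecoderConfig(),
    n_perm: int = 200,
    rng: np.random.Generator | None = None,
) -> RegionResults:
    """Run the full LOSO pipeline per region for both outcomes.

    Records, per region and outcome, the pooled prediction-vs-level
    correlation r, the number of pooled prediction points n, the
    concordance AUC and (when ``n_perm`` > 0) its permutation critical
    value for the conjunction analysis.
    """
    if rng is None and n_perm:
        raise DecodingError("permutation critical values require an rng")
    rows = []
    preds: dict[str, dict[int, pd.DataFrame]] = {"fear": {}, "scr": {}}
    datasets = {"fear": fear_dataset, "scr": scr_dataset}
    for region in range(parcellation.n_regions):
        voxels = parcellation.voxels_of(region)
        if voxels.size == 0:
            raise ValueError(f"region {region} has no voxels")
        row: dict = {"region": region}
        for outcome, dataset in datasets.items():
            sliced = _slice_dataset(dataset, voxels)
            res = loso_cv(sliced, config, n_perm=n_perm, rng=rng)
            r, n = _pooled_r(res.predictions)
            row[f"r_{outcome}"] = r
            row[f"n_{outcome}"] = n
            row[f"auc_{outcome}"] = res.auc
            row[f"critical_{outcome}"] = res.critical_value
            preds[outcome][region] = res.predictions
        rows.append(row)
    table = pd.DataFrame(rows)
    table = table.merge(parcellation.regions, on="region")
    return RegionResults(table, preds)


def _slice_dataset(dataset: BinnedDataset, voxels: np.ndarray) -> BinnedDataset:
    from .binning import SubjectBins

    bins = {
        s: SubjectBins(s, b.images[:, voxels], b.levels, b.counts)
        for s, b in dataset.bins.items()
    }
    return BinnedDataset(dataset.outcome, bins, dataset.centered, dict(dataset.flagged))


def preference_table(region_results: RegionResults, q: float = 0.05) -> pd.DataFrame:
    """Fisher-compare the two decoders per region and assign preferences.

    Adds Z (positive = fear better), two-sided p, Benjamini-Yekutieli
    adjusted q, delta_auc = auc_fear - auc_scr, and a preference label in
    {fear, scr, none} assigned by the sign of Z where the adjusted q falls
    below the threshold.  Correlations at |r| = 1 (degenerate) are flagged
    by a NaN Z.
    """
    table = region_results.table.copy()
    zs, ps = [], []
    for _, row in table.iterrows():
        try:
            z, p = fisher_z_compare(
                row["r_fear"], int(row["n_fear"]), row["r_scr"], int(row["n_scr"])
            )
        except ValueError as err:
            logger.warning("region %s: %s", row["region"], err)
            z, p = np.nan, 1.0
        zs.append(z)
        ps.append(p)
    table["Z"] = zs
    table["p"] = ps
    reject, qvals = by_fdr(table["p"].to_numpy(), q=q)
    table["q"] = qvals
    table["delta_auc"] = table["auc_fear"] - table["auc_scr"]
    pref = np.full(len(table), "none", dtype=object)
    pref[reject & (table["Z"].to_numpy() > 0)] = "fear"
    pref[reject & (table["Z"].to_numpy() < 0)] = "scr"
    table["preference"] = pref
    return table


def conjunction(region_results: RegionResults) -> pd.DataFrame:
    """Regions whose AUC exceeds its own permutation critical value for BOTH
    outcomes (the shared-representation conjunction)."""
    table = region_results.table
    if table["critical_fear"].isna().any() or table["critical_scr"].isna().any():
        raise ValueError("conjunction requires permutation critical values per outcome")
    out = table[["region", "name", "auc_fear", "critical_fear", "auc_scr", "critical_scr"]].copy()
    out["conjunction"] = (table["auc_fear"] > table["critical_fear"]) & (
        table["auc_scr"] > table["critical_scr"]
    )
    return out
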