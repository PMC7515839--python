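"""Standard-format I/O: BIDS-style events TSV, ratings CSV, electrodermal
trace CSV, NIfTI beta series / parcellation volumes, and results JSON."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .lss import TrialBetaMatrix
from .scr import SCRTrace
from .synth import ExperimentDesign, Parcellation


class FormatError(ValueError):
    pass


EVENT_COLUMNS = ["onset", "duration", "trial_type", "run", "chunk_first"]


def write_events_tsv(design: ExperimentDesign, path: str | Path) -> None:
    """Events table: onset, duration (0: impulse events), trial_type
    (category id), run, chunk_first, presentation, chunk_id."""
    s = design.schedule
    events = pd.DataFrame(
        {
            "onset": s["onset"],
            "duration": 0.0,
            "trial_type": s["category"],
            "run": s["run"],
            "chunk_first": s["chunk_first"].astype(int),
            "presentation": s["presentation"],
            "chunk_id": s["chunk_id"],
            "chunk_size": s["chunk_size"],
        }
    )
    events.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise FormatError(f"events file {path} is missing column(s) {missing}")
    frame = events.rename(columns={"trial_type": "category"}).copy()
    frame["chunk_first"] = frame["chunk_first"].astype(bool)
    if "presentation" not in frame:
        frame["presentation"] = frame.groupby("run").cumcount()
    return frame


def write_ratings_csv(ratings: pd.DataFrame, path: str | Path) -> None:
    long = ratings.stack().rename("rating").reset_index()
    long.to_csv(path, index=False)


def read_ratings_csv(path: str | Path) -> pd.DataFrame:
    long = pd.read_csv(path)
    for col in ("subject", "category", "rating"):
        if col not in long.columns:
            raise FormatError(f"ratings file {path} is missing column {col!r}")
    return long.pivot(index="subject", columns="category", values="rating").astype(int)


def write_trace_csv(trace: SCRTrace, path: str | Path) -> None:
    pd.DataFrame({"time": trace.times, "conductance": trace.samples}).to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> SCRTrace:
    frame = pd.read_csv(path)
    for col in ("time", "conductance"):
        if col not in frame.columns:
            raise FormatError(f"trace file {path} is missing column {col!r}")
    t = frame["time"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError("trace needs at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise FormatError("trace samples are not uniformly spaced")
    return SCRTrace(frame["conductance"].to_numpy(dtype=float), rate=1.0 / dt[0], start=float(t[0]))


def write_betas_nifti(betas: TrialBetaMatrix, path: str | Path) -> None:
    """Beta series as a voxels x 1 x 1 x trials NIfTI plus a trial-index TSV
    sidecar (same stem, .tsv)."""
    data = betas.betas.T[:, None, None, :].astype(np.float64)
    nib.save(nib.Nifti1Image(data, np.eye(4)), str(path))
    betas.trial_info.to_csv(Path(path).with_suffix("").with_suffix(".tsv"), sep="\t", index=False)


def read_betas_nifti(path: str | Path, subject: int = 0) -> TrialBetaMatrix:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError(f"{path}: expected a 4-D beta series, got shape {data.shape}")
    mat = data.reshape(data.shape[0] * data.shape[1] * data.shape[2], data.shape[3]).T
    sidecar = Path(path).with_suffix("").with_suffix(".tsv")
    if sidecar.exists():
        info = pd.read_csv(sidecar, sep="\t")
    else:
        info = pd.DataFrame({"run": 0, "presentation": np.arange(mat.shape[0]),
                             "onset": np.nan, "category": -1})
    if len(info) != mat.shape[0]:
        raise FormatError(f"{path}: trial sidecar rows do not match beta volumes")
    return TrialBetaMatrix(subject, mat, info)


def write_parcellation_nifti(parcellation: Parcellation, path: str | Path) -> None:
    data = (parcellation.voxel_region[:, None, None] + 1).astype(np.int32)  # 0 = background
    nib.save(nib.Nifti1Image(data, np.eye(4)), str(path))
    parcellation.regions.to_csv(Path(path).with_suffix("").with_suffix(".tsv"), sep="\t", index=False)


def read_parcellation_nifti(path: str | Path) -> Parcellation:
    """Load a label volume (0 = background, labels 1..K) as a parcellation
    over the flattened in-mask voxels."""
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).ravel().astype(int)
    labels = labels[labels > 0] - 1
    ids = np.unique(labels)
    sidecar = Path(path).with_suffix("").with_suffix(".tsv")
    if sidecar.exists():
        regions = pd.read_csv(sidecar, sep="\t")
    else:
        regions = pd.DataFrame(
            {"region": ids, "name": [f"region_{i:03d}" for i in ids],
             "hemisphere": ["?"] * len(ids)}
        )
    return Parcellation(labels, regions)


def write_summary_json(summary: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)!r}")
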