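"""Delimited-text I/O: cohorts, parcellations, matrices, result bundles.

Everything is plain text by design — the pipeline operates on extracted
vertex values, not images.  A cohort on disk is one vertex table per
subject per feature (columns ``vertex_id, roi_id, value``), a subject
manifest CSV with group and clinical columns, and an optional
ground-truth JSON sidecar recording planted effects and associations.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CLINICAL_VARIABLES, SubjectRecord
from .features import VertexFeatureMap

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_matrix",
    "read_matrix",
    "write_bundle",
    "default_parcellation",
    "ground_truth_dict",
]


def default_parcellation(n_roi: int = 210) -> pd.DataFrame:
    """Generic two-hemisphere cortical parcellation table (roi_id, name,
    hemisphere); odd ids left, even ids right, mirroring paired cortical
    atlas conventions."""
    ids = np.arange(1, n_roi + 1)
    hemi = np.where(ids % 2 == 1, "L", "R")
    names = [f"region_{i:03d}_{h}" for i, h in zip(ids, hemi)]
    return pd.DataFrame({"roi_id": ids, "name": names, "hemisphere": hemi})


def _vertex_path(outdir: Path, subject_id: str, feature: str) -> Path:
    return outdir / f"{subject_id}_{feature}.csv"


def ground_truth_dict(design) -> dict:
    """JSON-serializable record of a design's planted ground truth."""
    return {
        "seed": design.seed,
        "groups": [[g, n] for g, n in design.groups],
        "n_roi": design.n_roi,
        "features": list(design.features),
        "effects": [
            {"roi_id": e.roi_id, "feature": e.feature, "groups": list(e.groups),
             "kind": e.kind, "magnitude": e.magnitude}
            for e in design.effects
        ],
        "associations": [
            {"variable": a.variable, "roi_id": a.roi_id, "feature": a.feature,
             "rho": a.rho, "group": a.group, "summary": a.summary}
            for a in design.clinical_model
        ],
    }


def write_cohort(records, outdir, design=None) -> Path:
    """Write vertex tables, manifest, and (if a design is given) the
    ground-truth sidecar; returns the output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for rec in records:
        row = {"subject_id": rec.subject_id, "group": rec.group}
        row.update({v: rec.clinical.get(v, np.nan) for v in CLINICAL_VARIABLES})
        manifest_rows.append(row)
        for feature, vmap in rec.maps.items():
            df = pd.DataFrame({
                "vertex_id": np.arange(vmap.values.size),
                "roi_id": vmap.roi_labels,
                "value": vmap.values,
            })
            df.to_csv(_vertex_path(outdir, rec.subject_id, feature),
                      index=False, float_format="%.10g")
    pd.DataFrame(manifest_rows).to_csv(outdir / "manifest.csv", index=False)
    if design is not None:
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(ground_truth_dict(design), fh, indent=1, sort_keys=True)
    return outdir


def read_cohort(indir) -> list:
    """Read a cohort written by :func:`write_cohort` back into records."""
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    records = []
    for _, row in manifest.iterrows():
        sid = row["subject_id"]
        maps = {}
        for path in sorted(indir.glob(f"{sid}_*.csv")):
            feature = path.stem[len(sid) + 1:]
            df = pd.read_csv(path)
            maps[feature] = VertexFeatureMap(
                sid, feature,
                df["value"].to_numpy(float),
                df["roi_id"].to_numpy(int),
            )
        clinical = {v: float(row[v]) for v in CLINICAL_VARIABLES if v in row}
        records.append(SubjectRecord(sid, row["group"], clinical, maps))
    return records


def write_matrix(M: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(M, float), delimiter="\t", fmt="%.12g")


def read_matrix(path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t")


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="records"))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_bundle(bundle: dict, path) -> Path:
    """Serialize a results bundle (dict of DataFrames / dicts) to JSON with
    stable key ordering, so identical runs produce identical bytes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(bundle), fh, indent=1, sort_keys=True)
    return path
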