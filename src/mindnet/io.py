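"""Plain-text readers/writers for the pipeline's table formats.

Everything is TSV/CSV/GMT/JSON so runs are diffable and portable:
vertex features (vertex_id, region_id, ct, gmv, mc, sa, sd), phenotype CSV,
centroid TSV, regions x genes expression TSV, square MIND matrix TSV, and
regional-profile TSV.  Headers carry the conventions (t-sign, sidedness)
where results are written.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ParcellationGeometry
from .mind import FEATURE_NAMES, MINDMatrix, VertexFeatureSet
from .pls import ExpressionMatrix

_FEATURE_COLS = [f.lower() for f in FEATURE_NAMES]


def write_vertex_features(fs: VertexFeatureSet, path) -> None:
    df = pd.DataFrame(fs.features, columns=_FEATURE_COLS)
    df.insert(0, "region_id", np.asarray(fs.region_ids)[fs.vertex_region_idx])
    df.insert(0, "vertex_id", np.arange(len(df)))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_vertex_features(path, subject_id: str | None = None) -> VertexFeatureSet:
    df = pd.read_csv(path, sep="\t")
    region_ids = pd.unique(df["region_id"])
    idx = pd.Series(np.arange(len(region_ids)), index=region_ids)
    return VertexFeatureSet(
        subject_id=subject_id or Path(path).stem,
        features=df[_FEATURE_COLS].to_numpy(dtype=float),
        region_ids=np.asarray(region_ids),
        vertex_region_idx=idx[df["region_id"]].to_numpy(),
    )


def write_centroids(geometry: ParcellationGeometry, path) -> None:
    df = pd.DataFrame(geometry.centroids, columns=["x", "y", "z"])
    df.insert(0, "hemi", geometry.hemisphere)
    df.insert(0, "region_id", geometry.region_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def write_matrix(m: MINDMatrix, path) -> None:
    """Square similarity matrix with region-id header row/column."""
    df = pd.DataFrame(m.values, index=m.region_ids, columns=m.region_ids)
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_matrix(path) -> MINDMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return MINDMatrix(
        values=df.to_numpy(dtype=float), region_ids=np.asarray(df.index)
    )


def write_profiles(profiles: pd.DataFrame, path) -> None:
    """Regions x subjects table of regional MIND (weighted node degree)."""
    profiles.to_csv(path, sep="\t", index_label="region_id",
                    float_format="%.10g")


def read_profiles(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="region_id")


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().to_csv(path, sep="\t", float_format="%.10g")


def read_expression(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="region_id")
    return ExpressionMatrix(
        region_ids=np.asarray(df.index),
        gene_ids=np.asarray(df.columns),
        values=df.to_numpy(dtype=float),
    )


def write_contrast(cm, path) -> None:
    df = cm.to_frame()
    with open(path, "w") as fh:
        fh.write("# t > 0 means patient > control; p two-sided; "
                 f"p_bonf = min(1, {len(df)} * p)\n")
        df.to_csv(fh, sep="\t", float_format="%.10g")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
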