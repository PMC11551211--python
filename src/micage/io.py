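"""Readers and writers for the pipeline's plain-text formats.

Feature tables are TSV with features as rows and samples as columns (the
common amplicon convention); orientation is auto-detected against the
sample metadata and logged.  Trees are newick, peak/Ct/reference tables
CSV, images 16-bit TIFF, results JSON, metabolite sets GMT.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import skbio
import tifffile

from .community import FeatureTable
from .integration import MetaboliteSet
from .metabolome import MetaboliteReference, PeakTable

logger = logging.getLogger("micage")


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def read_metadata(path) -> pd.Series:
    """Sample metadata TSV with columns sample_id and group."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    need = {"sample_id", "group"}
    if not need <= set(meta.columns):
        raise ValueError(f"metadata needs columns {sorted(need)}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    return meta.set_index("sample_id")["group"]


def read_feature_table(path, metadata, kind: str = "taxa",
                       orientation: str = "auto") -> FeatureTable:
    """TSV feature table + metadata -> validated FeatureTable.

    ``orientation`` 'features' (rows are features), 'samples', or 'auto'
    (chosen by matching metadata sample ids against rows vs columns).
    """
    groups = metadata if isinstance(metadata, pd.Series) else read_metadata(metadata)
    raw = pd.read_csv(path, sep="\t", index_col=0)
    if not all(np.issubdtype(dt, np.number) for dt in raw.dtypes):
        bad = [c for c in raw.columns
               if not np.issubdtype(raw[c].dtype, np.number)]
        raise ValueError(f"non-numeric cells in columns {bad}")
    if orientation == "auto":
        in_cols = len(set(groups.index) & set(raw.columns))
        in_rows = len(set(groups.index) & set(raw.index))
        orientation = "features" if in_cols >= in_rows else "samples"
        logger.info("read_feature_table: detected %s-as-rows orientation",
                    "feature" if orientation == "features" else "sample")
    data = raw.T if orientation == "features" else raw
    missing = set(data.index) - set(groups.index)
    if missing:
        raise ValueError(f"samples missing metadata: {sorted(missing)}")
    return FeatureTable(data, groups.loc[data.index], kind=kind)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write features-as-rows TSV (header row of sample ids)."""
    table.data.T.to_csv(path, sep="\t", index_label="feature_id")


def write_metadata(groups: pd.Series, path) -> None:
    groups.rename("group").to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# trees / distance matrices
# ---------------------------------------------------------------------------

def read_tree(path) -> skbio.TreeNode:
    return skbio.TreeNode.read(str(path))


def write_tree(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path))


def write_distance_matrix(dm: skbio.DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# peak tables / references
# ---------------------------------------------------------------------------

def read_peak_table(features_path, intensities_path, metadata) -> PeakTable:
    """Feature CSV (feature_id, mz, rt, mode) + intensity CSV (samples x features)."""
    groups = metadata if isinstance(metadata, pd.Series) else read_metadata(metadata)
    features = pd.read_csv(features_path, index_col=0)
    intensities = pd.read_csv(intensities_path, index_col=0)
    return PeakTable(features, intensities, groups.loc[intensities.index])


def write_peak_table(peaks: PeakTable, features_path, intensities_path) -> None:
    peaks.features.to_csv(features_path, index_label="feature_id")
    peaks.intensities.to_csv(intensities_path, index_label="sample_id")


def read_reference(path) -> MetaboliteReference:
    """Metabolite reference CSV: name, hmdb_id, kegg_id, mass, pathways
    (semicolon-joined), superclass."""
    return MetaboliteReference(pd.read_csv(path, index_col="name"))


def write_reference(ref: MetaboliteReference, path) -> None:
    out = ref.table.copy()
    out["pathways"] = out["pathways"].apply(";".join)
    out.to_csv(path, index_label="name")


# ---------------------------------------------------------------------------
# GMT metabolite sets
# ---------------------------------------------------------------------------

def write_gmt(sets: list[MetaboliteSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            desc = "pathways:" + ",".join(s.source_pathways)
            fh.write("\t".join([s.superclass_id, desc, *s.members]) + "\n")


def read_gmt(path) -> list[MetaboliteSet]:
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, desc, *members = line.split("\t")
        pws = desc.removeprefix("pathways:").split(",") if desc else []
        sets.append(MetaboliteSet(name, members, [p for p in pws if p]))
    return sets


# ---------------------------------------------------------------------------
# images / json
# ---------------------------------------------------------------------------

def write_tiff(raster: np.ndarray, path) -> None:
    tifffile.imwrite(str(path), np.asarray(raster, dtype=np.uint16))


def read_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default, allow_nan=True)
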