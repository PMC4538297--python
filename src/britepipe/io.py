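"""Readers and writers for the pipeline's on-disk formats.

Plain-text formats throughout: TSV matrices (probe_id first column,
"NA" for missing), TSV metadata and bead tables, standard GMT gene-set
files (name, description, tab-separated members), CSV qPCR tables, JSON
truth/report files; image stacks as multi-page TIFF with a JSON sidecar
naming the channels and voxel sizes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd
import tifffile

from .beadarray import ExpressionMatrix
from .fish import VoxelStack
from .gsea import GeneSet, GeneSetCollection


# ---------------------------------------------------------------- expression

def write_matrix_tsv(m: ExpressionMatrix, path) -> None:
    m.to_tsv(path)


def read_matrix_tsv(path, scale: str = "linear") -> ExpressionMatrix:
    return ExpressionMatrix.from_tsv(path, scale=scale)


def write_bead_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_bead_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"probe_id", "sample_id", "bead_value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: bead table missing columns {sorted(missing)}")
    return df


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"sample_id", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: metadata missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------- GMT

def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


def read_gmt(path) -> GeneSetCollection:
    sets: List[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT record needs name, description and >=1 member"
                )
            sets.append(GeneSet(fields[0], fields[1], tuple(fields[2:])))
    return GeneSetCollection(sets)


# --------------------------------------------------------------------- qPCR

def write_qpcr_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_qpcr_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"sample_id", "gene", "ct"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: qPCR table missing columns {sorted(missing)}")
    return df


# ------------------------------------------------------------------- images

def write_stack(stack: VoxelStack, tiff_path) -> None:
    """Multi-page TIFF (pages = c*z, CZYX order) plus a JSON sidecar."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(
        tiff_path, stack.data, photometric="minisblack", metadata={"axes": "CZYX"}
    )
    sidecar = {
        "channels": dict(stack.channels),
        "xy_nm": stack.xy_nm,
        "z_nm": stack.z_nm,
        "shape_czyx": list(stack.data.shape),
    }
    tiff_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_stack(tiff_path) -> VoxelStack:
    tiff_path = Path(tiff_path)
    sidecar_path = tiff_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"channel-map sidecar {sidecar_path} not found")
    sidecar = json.loads(sidecar_path.read_text())
    data = tifffile.imread(tiff_path)
    data = np.asarray(data, dtype=np.float32).reshape(sidecar["shape_czyx"])
    return VoxelStack(
        data=data,
        channels={k: int(v) for k, v in sidecar["channels"].items()},
        xy_nm=float(sidecar["xy_nm"]),
        z_nm=float(sidecar["z_nm"]),
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
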