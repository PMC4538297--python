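"""Bead-array preprocessing: bead-level summarization and normalization.

The summarization rule follows the array platform's bead-level protocol:
beads with intensity strictly above a floor (default 20) are selected,
outliers deviating from the median by more than 2.5 raw (unscaled) median
absolute deviations are removed, and the remaining beads are averaged to
give the probe signal. Columns are then made distributionally identical
by quantile normalization, and downstream statistics operate on log2
intensities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class ExpressionMatrix:
    """Probe x sample intensity grid.

    ``data`` is a probes-by-samples DataFrame; missing cells are NaN.
    ``scale`` records whether values are linear intensities or log2.
    """

    data: pd.DataFrame
    scale: str = "linear"  # "linear" | "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        self.data = self.data.astype(float)

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy(), self.scale)

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path, scale: str = "linear") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return cls(df, scale)


def summarize_probe(
    bead_values: Iterable[float], floor: float = 20.0, mad_k: float = 2.5
) -> float:
    """Summarize one probe's bead intensities to a single signal.

    Keeps beads strictly > ``floor``, removes beads whose absolute
    deviation from the median exceeds ``mad_k`` times the raw MAD, and
    returns the mean of the remainder. Returns NaN when nothing survives.
    """
    x = np.asarray(list(bead_values), dtype=float)
    if x.size and (not np.all(np.isfinite(x)) or np.any(x < 0)):
        raise ValueError("bead values must be finite and nonnegative")
    x = x[x > floor]
    if x.size == 0:
        return float("nan")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    keep = np.abs(x - med) <= mad_k * mad
    x = x[keep]
    if x.size == 0:  # unreachable: the median itself always survives
        return float("nan")
    return float(np.mean(x))


def summarize_table(
    table: pd.DataFrame, floor: float = 20.0, mad_k: float = 2.5
) -> ExpressionMatrix:
    """Summarize a long bead table (probe_id, sample_id, bead_value) to a matrix.

    Duplicate (probe, sample) bead groups are pooled. Cells where no bead
    survives the floor are recorded as missing (NaN).
    """
    required = {"probe_id", "sample_id", "bead_value"}
    if not required.issubset(table.columns):
        raise ValueError(f"bead table must have columns {sorted(required)}")
    vals = table["bead_value"].to_numpy(dtype=float)
    if vals.size and (not np.all(np.isfinite(vals)) or np.any(vals < 0)):
        raise ValueError("bead values must be finite and nonnegative")

    probes = pd.unique(table["probe_id"])
    samples = pd.unique(table["sample_id"])

    t = table.loc[vals > floor, ["probe_id", "sample_id", "bead_value"]].copy()
    grp = t.groupby(["probe_id", "sample_id"], sort=False)["bead_value"]
    med = grp.transform("median")
    absdev = (t["bead_value"] - med).abs()
    mad = absdev.groupby([t["probe_id"], t["sample_id"]], sort=False).transform("median")
    keep = absdev <= mad_k * mad
    means = (
        t.loc[keep]
        .groupby(["probe_id", "sample_id"], sort=False)["bead_value"]
        .mean()
        .unstack("sample_id")
    )
    means = means.reindex(index=probes, columns=samples)
    means.index.name = "probe_id"
    return ExpressionMatrix(means, scale="linear")


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the common (row-mean) distribution.

    Ties within a column receive the mean of the reference values at
    their tied ranks. Missing cells are imputed with the column median
    for the rank computation and re-masked afterwards, so they never
    leak into downstream statistics.
    """
    df = m.data
    if df.shape[1] <= 1:
        return m.copy()
    mask = df.isna()
    filled = df.apply(lambda c: c.fillna(c.median()), axis=0)
    arr = filled.to_numpy(dtype=float)
    n = arr.shape[0]
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    grid = np.arange(n, dtype=float)
    for j in range(arr.shape[1]):
        ranks = rankdata(arr[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, grid, ref)
    res = pd.DataFrame(out, index=df.index, columns=df.columns)
    res[mask] = np.nan
    return ExpressionMatrix(res, m.scale)


def log2_transform(m: ExpressionMatrix, floor: float = 1.0) -> ExpressionMatrix:
    """Elementwise log2. Values <= 0 are clamped to ``floor`` first.

    Refuses log2-scale input to guard against double transformation.
    """
    if m.scale == "log2":
        raise ValueError("matrix is already on the log2 scale")
    vals = m.data.mask(m.data <= 0, floor)  # missing cells stay missing
    return ExpressionMatrix(np.log2(vals), scale="log2")
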