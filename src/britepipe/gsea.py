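"""Gene-set enrichment analysis with phenotype permutation.

The engine reproduces the canonical parameterization: genes are ranked
by the Signal2Noise metric (difference of group means over the sum of
floored standard deviations), the enrichment score (ES) is the signed
maximum deviation of a weighted running sum (hits weighted by
|metric|^weight, misses by 1/(N - Nh)), the null is built by permuting
the phenotype labels and recomputing the ranking, NES divides ES by the
mean same-sign null ES magnitude ("meandiv"), and the FDR q-value
compares the observed NES distribution against the pooled normalized
null distribution. Gene sets are reported ranked by FDR.

When fewer distinct label assignments exist than requested permutations
(e.g. 3 vs 3 gives C(6,3) = 20), all distinct assignments are enumerated
exactly once and a warning is recorded; the assignment equal to the
observed labeling is excluded from the null distribution itself, so
permutation FDR resolution is not floored by the observed labeling
re-entering its own null (the convention is documented in the methods
note). Gene-set permutation is available as an explicit alternative
mode; it is never substituted silently.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .beadarray import ExpressionMatrix


@dataclass
class GeneSet:
    name: str
    description: str
    members: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            self.members = tuple(dict.fromkeys(self.members))


@dataclass
class GeneSetCollection:
    sets: List[GeneSet]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ValueError("gene set names must be unique within a collection")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> List[str]:
        return [s.name for s in self.sets]


@dataclass
class RankedList:
    """Genes ordered by nonincreasing metric value."""

    genes: np.ndarray
    metric: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.metric):
            raise ValueError("genes and metric lengths differ")
        if np.any(np.diff(self.metric) > 1e-12):
            raise ValueError("metric must be nonincreasing")
        if len(set(self.genes.tolist())) != len(self.genes):
            raise ValueError("gene ids must be unique")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ESProfile:
    set_name: str
    running: np.ndarray  # running-sum value after each ranked position
    es: float
    es_index: int
    leading_edge: Tuple[str, ...]
    size: int  # members present in the ranked list


@dataclass
class GseaRecord:
    name: str
    size: int
    es: float
    nes: float
    fdr_q: float
    p_nominal: float


@dataclass
class PermutationNull:
    """Null ES matrix (sets x assignments) from label permutation."""

    es: np.ndarray
    set_names: List[str]
    assignments: List[Tuple[int, ...]]
    exhaustive: bool
    observed_index: Optional[int]
    warning: Optional[str] = None


@dataclass
class GseaReport:
    records: List[GseaRecord]  # sorted by FDR q, then |NES| descending
    profiles: Dict[str, ESProfile]
    skipped: List[Tuple[str, int, str]]  # (set name, size in list, reason)
    exhaustive: bool
    n_assignments: int
    warning: Optional[str] = None

    @property
    def up(self) -> List[GseaRecord]:
        return [r for r in self.records if r.es > 0]

    @property
    def down(self) -> List[GseaRecord]:
        return [r for r in self.records if r.es < 0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": r.name,
                    "size": r.size,
                    "es": r.es,
                    "nes": r.nes,
                    "fdr_q": r.fdr_q,
                    "p_nominal": r.p_nominal,
                }
                for r in self.records
            ]
        )


def signal2noise_ranking(
    m: ExpressionMatrix,
    meta: pd.DataFrame,
    group_a: str,
    group_b: str,
    sd_floor_frac: float = 0.2,
    sd_floor_abs: float = 0.2,
) -> RankedList:
    """Rank genes by (mu_A - mu_B) / (sigma_A + sigma_B), descending.

    Each group standard deviation is floored at
    max(sd_floor_frac * |mu|, sd_floor_abs), the metric's standard guard
    against near-zero denominators. Ties are broken by gene id.
    """
    cols_a, cols_b = _group_columns(m, meta, group_a, group_b)
    genes = np.asarray(m.probe_ids)
    A = m.data[cols_a].to_numpy(dtype=float)
    B = m.data[cols_b].to_numpy(dtype=float)
    metric, ok = _s2n(A, B, sd_floor_frac, sd_floor_abs)
    genes, metric = genes[ok], metric[ok]
    order = np.lexsort((genes, -metric))
    return RankedList(genes[order], metric[order])


def _group_columns(m, meta, group_a, group_b):
    by_group = meta.groupby("group")["sample_id"].apply(list).to_dict()
    for g in (group_a, group_b):
        if g not in by_group:
            raise ValueError(f"group {g!r} absent from metadata")
    in_matrix = set(m.sample_ids)
    cols_a = [s for s in by_group[group_a] if s in in_matrix]
    cols_b = [s for s in by_group[group_b] if s in in_matrix]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >=2 samples per group for Signal2Noise")
    return cols_a, cols_b


def _s2n(A: np.ndarray, B: np.ndarray, frac: float, absfloor: float):
    """Vectorized Signal2Noise over rows; returns (metric, finite mask)."""
    import warnings

    na = np.sum(np.isfinite(A), axis=1)
    nb = np.sum(np.isfinite(B), axis=1)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows masked below
        mu_a = np.nanmean(A, axis=1)
        mu_b = np.nanmean(B, axis=1)
        sd_a = np.nanstd(A, axis=1, ddof=1)
        sd_b = np.nanstd(B, axis=1, ddof=1)
    sd_a = np.maximum(np.maximum(sd_a, frac * np.abs(mu_a)), absfloor)
    sd_b = np.maximum(np.maximum(sd_b, frac * np.abs(mu_b)), absfloor)
    metric = (mu_a - mu_b) / (sd_a + sd_b)
    ok = (na >= 2) & (nb >= 2) & np.isfinite(metric)
    return metric, ok


def enrichment_score(
    rl: RankedList, gene_set: GeneSet, weight: float = 1.0
) -> ESProfile:
    """Weighted Kolmogorov-Smirnov-style running sum over the ranked list.

    Hits add |metric|^weight normalized by the in-set total; misses
    subtract 1/(N - Nh). The ES is the running-sum value of largest
    absolute deviation from zero (first such position; an exact
    positive/negative magnitude tie resolves positive); the leading edge
    is the set members at or before (positive ES) / at or after
    (negative ES) the extremum.
    """
    member_set = set(gene_set.members)
    hit = np.fromiter((g in member_set for g in rl.genes), dtype=bool, count=len(rl))
    nh = int(hit.sum())
    n = len(rl)
    if nh == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no members in the ranked list")
    running = _running_sum(rl.metric, hit, weight, n, nh)
    i, es = _extremum(running)
    if es >= 0:
        le = tuple(rl.genes[: i + 1][hit[: i + 1]])
    else:
        le = tuple(rl.genes[i:][hit[i:]])
    return ESProfile(gene_set.name, running, es, i, le, nh)


def _running_sum(metric, hit, weight, n, nh) -> np.ndarray:
    if weight == 0:
        w = np.ones(n)
    else:
        w = np.abs(metric) ** weight
    wh = np.where(hit, w, 0.0)
    denom = wh.sum()
    if denom <= 0:  # all in-set metrics zero: fall back to unweighted hits
        wh = hit.astype(float)
        denom = wh.sum()
    p_hit = np.cumsum(wh) / denom
    if n > nh:
        p_miss = np.cumsum(~hit) / (n - nh)
    else:
        p_miss = np.zeros(n)
    return p_hit - p_miss


def _extremum(running: np.ndarray) -> Tuple[int, float]:
    """First position of the max |running sum|; exact +- ties go positive."""
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        return i_max, float(running[i_max])
    return i_min, float(running[i_min])


def _es_only(metric, hit, weight) -> float:
    n = len(metric)
    nh = int(hit.sum())
    if nh == 0:
        return np.nan
    running = _running_sum(metric, hit, weight, n, nh)
    return _extremum(running)[1]


def phenotype_permutation_null(
    m: ExpressionMatrix,
    meta: pd.DataFrame,
    collection: GeneSetCollection,
    group_a: str,
    group_b: str,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    weight: float = 1.0,
    sd_floor_frac: float = 0.2,
    sd_floor_abs: float = 0.2,
) -> PermutationNull:
    """Null ES per set per label assignment.

    When the number of distinct label assignments is <= ``n_perm``, all
    of them are enumerated exactly once (with a recorded warning) and
    the observed assignment's column index is reported so it can be
    excluded from null statistics; otherwise ``n_perm`` assignments are
    sampled with the given seed.
    """
    cols_a, cols_b = _group_columns(m, meta, group_a, group_b)
    cols = cols_a + cols_b
    na, n = len(cols_a), len(cols_a) + len(cols_b)
    X = m.data[cols].to_numpy(dtype=float)
    genes = np.asarray(m.probe_ids)

    total = math.comb(n, na)
    warning = None
    observed_index: Optional[int] = None
    if total <= n_perm:
        assignments = [tuple(c) for c in itertools.combinations(range(n), na)]
        exhaustive = True
        observed_index = assignments.index(tuple(range(na)))
        warning = (
            f"only {total} distinct label assignments exist for "
            f"{na} vs {n - na}; enumerating all of them instead of "
            f"{n_perm} random permutations"
        )
    else:
        rng = np.random.default_rng(seed)
        assignments = [
            tuple(sorted(rng.choice(n, size=na, replace=False))) for _ in range(n_perm)
        ]
        exhaustive = False

    member_masks = []
    gene_index = {g: i for i, g in enumerate(genes)}
    for s in collection:
        mask = np.zeros(len(genes), dtype=bool)
        for g in s.members:
            j = gene_index.get(g)
            if j is not None:
                mask[j] = True
        member_masks.append(mask)

    null = np.full((len(collection.sets), len(assignments)), np.nan)
    all_idx = np.arange(n)
    for c, assign in enumerate(assignments):
        ia = np.asarray(assign, dtype=int)
        ib = np.setdiff1d(all_idx, ia, assume_unique=True)
        metric, ok = _s2n(X[:, ia], X[:, ib], sd_floor_frac, sd_floor_abs)
        order = np.lexsort((genes[ok], -metric[ok]))
        sorted_metric = metric[ok][order]
        ok_pos = np.flatnonzero(ok)[order]
        for si, mask in enumerate(member_masks):
            hit = mask[ok_pos]
            if hit.any():
                null[si, c] = _es_only(sorted_metric, hit, weight)
    return PermutationNull(
        es=null,
        set_names=collection.names,
        assignments=assignments,
        exhaustive=exhaustive,
        observed_index=observed_index,
        warning=warning,
    )


def normalize_and_fdr(
    set_names: Sequence[str],
    sizes: Sequence[int],
    observed_es: Sequence[float],
    null_es: np.ndarray,
    exclude_column: Optional[int] = None,
    leave_one_out: bool = False,
) -> List[GseaRecord]:
    """meandiv normalization, nominal p, and permutation FDR q.

    NES = ES / mean(same-sign null ES magnitudes of that set); nominal p
    is the same-sign null tail fraction; q compares the tail fraction of
    the pooled normalized null NES with the tail fraction of the observed
    NES distribution, clipped to [0, 1]. A set with no same-sign null
    values gets NaN NES and q 1 (flagged by the NaN).

    With ``leave_one_out`` (used for exhaustive small-n permutation,
    where few null columns exist) each null column's NES is normalized by
    the same-sign means of the *other* columns, matching the observed
    ES's out-of-sample normalization so observed and null NES stay
    exchangeable under the null; with enough sampled permutations the
    in-sample bias is negligible and the plain pooled means are used.
    """
    null = np.asarray(null_es, dtype=float)
    if exclude_column is not None:
        null = np.delete(null, exclude_column, axis=1)
    observed_es = np.asarray(observed_es, dtype=float)
    nsets = len(set_names)
    if null.shape[0] != nsets:
        raise ValueError("null matrix rows must match number of sets")

    finite = np.isfinite(null)
    pos = finite & (null > 0)
    neg = finite & (null < 0)
    pos_sum = np.where(pos, null, 0.0).sum(axis=1)
    neg_sum = np.where(neg, -null, 0.0).sum(axis=1)
    pos_n = pos.sum(axis=1)
    neg_n = neg.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_pos = np.where(pos_n > 0, pos_sum / np.maximum(pos_n, 1), np.nan)
        mean_neg = np.where(neg_n > 0, neg_sum / np.maximum(neg_n, 1), np.nan)

    def _nes(es: float, i: int) -> float:
        if es > 0:
            return es / mean_pos[i]
        if es < 0:
            return es / mean_neg[i]
        return 0.0

    obs_nes = np.array([_nes(observed_es[i], i) for i in range(nsets)])
    null_nes = np.full_like(null, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        if leave_one_out:
            loo_mean_pos = (pos_sum[:, None] - np.where(pos, null, 0.0)) / np.maximum(
                pos_n[:, None] - pos.astype(int), 1
            )
            loo_mean_neg = (neg_sum[:, None] - np.where(neg, -null, 0.0)) / np.maximum(
                neg_n[:, None] - neg.astype(int), 1
            )
            div_pos, div_neg = loo_mean_pos, loo_mean_neg
        else:
            div_pos = np.broadcast_to(mean_pos[:, None], null.shape)
            div_neg = np.broadcast_to(mean_neg[:, None], null.shape)
        null_nes[pos] = (null / div_pos)[pos]
        null_nes[neg] = (null / div_neg)[neg]
        null_nes[finite & (null == 0)] = 0.0

    p_nom = np.full(nsets, np.nan)
    for i in range(nsets):
        row = null[i][np.isfinite(null[i])]
        es = observed_es[i]
        if es > 0:
            pos = row[row > 0]
            p_nom[i] = float(np.mean(pos >= es)) if pos.size else np.nan
        elif es < 0:
            neg = row[row < 0]
            p_nom[i] = float(np.mean(neg <= es)) if neg.size else np.nan
        else:
            p_nom[i] = 1.0

    pooled = null_nes[np.isfinite(null_nes)]
    pooled_pos = pooled[pooled > 0]
    pooled_neg = pooled[pooled < 0]
    obs_ok = obs_nes[np.isfinite(obs_nes)]
    obs_pos = obs_ok[obs_ok > 0]
    obs_neg = obs_ok[obs_ok < 0]

    records = []
    for i, name in enumerate(set_names):
        nes = obs_nes[i]
        if not np.isfinite(nes):
            q = 1.0
        elif nes > 0:
            num = float(np.mean(pooled_pos >= nes)) if pooled_pos.size else 0.0
            den = float(np.mean(obs_pos >= nes)) if obs_pos.size else 1.0
            q = min(1.0, max(0.0, num / den)) if den > 0 else 1.0
        elif nes < 0:
            num = float(np.mean(pooled_neg <= nes)) if pooled_neg.size else 0.0
            den = float(np.mean(obs_neg <= nes)) if obs_neg.size else 1.0
            q = min(1.0, max(0.0, num / den)) if den > 0 else 1.0
        else:
            q = 1.0
        records.append(
            GseaRecord(
                name=name,
                size=int(sizes[i]),
                es=float(observed_es[i]),
                nes=float(nes) if np.isfinite(nes) else float("nan"),
                fdr_q=float(q),
                p_nominal=float(p_nom[i]) if np.isfinite(p_nom[i]) else float("nan"),
            )
        )
    return records


def run_gsea(
    m: ExpressionMatrix,
    meta: pd.DataFrame,
    collection: GeneSetCollection,
    group_a: str,
    group_b: str,
    weight: float = 1.0,
    n_perm: int = 1000,
    min_size: int = 15,
    max_size: int = 500,
    seed: Optional[int] = None,
    permutation: str = "phenotype",
    sd_floor_frac: float = 0.2,
    sd_floor_abs: float = 0.2,
) -> GseaReport:
    """Full GSEA run: ranking, ES, permutation null, NES/FDR, report.

    Sets whose membership in the ranked list falls outside
    [min_size, max_size] are skipped and logged. Records are sorted by
    FDR q, then |NES| descending, then name.
    """
    rl = signal2noise_ranking(m, meta, group_a, group_b, sd_floor_frac, sd_floor_abs)
    in_list = set(rl.genes.tolist())
    scored, skipped = [], []
    for s in collection:
        size = len([g for g in s.members if g in in_list])
        if size == 0:
            skipped.append((s.name, 0, "no members in ranked list"))
        elif size < min_size:
            skipped.append((s.name, size, f"size {size} < min_size {min_size}"))
        elif size > max_size:
            skipped.append((s.name, size, f"size {size} > max_size {max_size}"))
        else:
            scored.append(s)
    if not scored:
        return GseaReport([], {}, skipped, False, 0, warning="no sets to score")
    sub = GeneSetCollection(scored)

    profiles = {s.name: enrichment_score(rl, s, weight) for s in sub}
    observed = [profiles[s.name].es for s in sub]
    sizes = [profiles[s.name].size for s in sub]

    if permutation == "phenotype":
        null = phenotype_permutation_null(
            m, meta, sub, group_a, group_b, n_perm=n_perm, seed=seed,
            weight=weight, sd_floor_frac=sd_floor_frac, sd_floor_abs=sd_floor_abs,
        )
        null_es = null.es
        exclude = null.observed_index if null.exhaustive else None
        exhaustive, n_assign, warning = null.exhaustive, len(null.assignments), null.warning
    elif permutation == "gene_set":
        null_es = _gene_set_permutation_null(rl, sub, n_perm, seed, weight)
        exclude, exhaustive, n_assign, warning = None, False, n_perm, None
    else:
        raise ValueError(f"unknown permutation mode {permutation!r}")

    records = normalize_and_fdr(
        sub.names, sizes, observed, null_es,
        exclude_column=exclude, leave_one_out=exhaustive,
    )
    records.sort(key=lambda r: (r.fdr_q, -abs(r.nes) if np.isfinite(r.nes) else 0.0, r.name))
    return GseaReport(records, profiles, skipped, exhaustive, n_assign, warning)


def _gene_set_permutation_null(rl, collection, n_perm, seed, weight) -> np.ndarray:
    """Alternative null: random member sets of matched size from the list."""
    rng = np.random.default_rng(seed)
    n = len(rl)
    null = np.full((len(collection.sets), n_perm), np.nan)
    for si, s in enumerate(collection):
        size = len([g for g in s.members if g in set(rl.genes.tolist())])
        for c in range(n_perm):
            hit = np.zeros(n, dtype=bool)
            hit[rng.choice(n, size=size, replace=False)] = True
            null[si, c] = _es_only(rl.metric, hit, weight)
    return null


def es_trajectory(
    matrices: Mapping[str, ExpressionMatrix],
    meta: pd.DataFrame,
    collection: GeneSetCollection,
    set_names: Sequence[str],
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    **gsea_params,
) -> pd.DataFrame:
    """ES / FDR q time-course per gene set: one GSEA run per timepoint.

    ``matrices`` maps timepoint label to the (log2) matrix of that
    timepoint's samples. Timepoints where a group is missing are skipped
    with a recorded reason. Returns a table of (set, timepoint, es, nes,
    fdr_q, significant) with significance flagged at q < ``alpha``.
    """
    unknown = [n for n in set_names if n not in collection.names]
    if unknown:
        raise ValueError(f"sets not in collection: {unknown}")
    rows = []
    for tp, matrix in matrices.items():
        sub_meta = meta[meta["sample_id"].isin(matrix.sample_ids)]
        try:
            report = run_gsea(matrix, sub_meta, collection, group_a, group_b, **gsea_params)
        except ValueError as err:
            rows.append(
                {"set": None, "timepoint": tp, "es": np.nan, "nes": np.nan,
                 "fdr_q": np.nan, "significant": False, "note": str(err)}
            )
            continue
        by_name = {r.name: r for r in report.records}
        for name in set_names:
            r = by_name.get(name)
            if r is None:
                rows.append({"set": name, "timepoint": tp, "es": np.nan, "nes": np.nan,
                             "fdr_q": np.nan, "significant": False, "note": "skipped"})
            else:
                rows.append({"set": name, "timepoint": tp, "es": r.es, "nes": r.nes,
                             "fdr_q": r.fdr_q, "significant": bool(r.fdr_q < alpha),
                             "note": ""})
    return pd.DataFrame(rows)


def split_by_timepoint(m: ExpressionMatrix, meta: pd.DataFrame) -> Dict[str, ExpressionMatrix]:
    """Partition a matrix into per-timepoint matrices using the metadata."""
    out = {}
    for tp, sub in meta.groupby("timepoint", sort=False):
        cols = [s for s in m.sample_ids if s in set(sub["sample_id"])]
        if cols:
            out[tp] = ExpressionMatrix(m.data[cols], m.scale)
    return out
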