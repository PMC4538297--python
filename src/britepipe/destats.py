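"""Two-group differential expression and qPCR quantification.

The moderated t-test shrinks per-probe variances toward a common prior
fitted by moment matching on the log variances (a scaled-inverse-chi-square
hierarchical model): the posterior variance is

    s~^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

with prior degrees of freedom ``d0`` and prior variance ``s0^2`` estimated
from the ensemble of per-probe pooled variances, and the moderated
statistic referred to a t distribution on d0 + d degrees of freedom.
With d0 = 0 this reduces exactly to the classical pooled two-sample t.
P-values are adjusted by the Holm step-down procedure.

Relative qPCR expression uses the delta-delta-Ct method against a
reference gene and a calibrator group: fold = 2^(-ddCt).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .beadarray import ExpressionMatrix


@dataclass
class DEResult:
    """Per-probe differential expression between two groups (A - B)."""

    table: pd.DataFrame  # mean_a, mean_b, log2fc, t_mod, df_total, p_raw, p_holm, excluded
    group_a: str
    group_b: str
    prior_df: float
    prior_var: float

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t", na_rep="NA")


@dataclass
class ConcordanceResult:
    """Probes significant in two independent comparisons, with paired ratios."""

    selected: list  # probe ids significant in both comparisons
    pairs: pd.DataFrame  # log2ratio_a, log2ratio_b for the selected probes
    n_regulated_in_a: int
    n_selected: int
    sign_agreement: float


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from per-probe variances with residual df.

    Works on z = log(s^2): E[z] and Var[z] under the hierarchical model
    involve digamma/trigamma terms of d/2 and d0/2.
    """
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return np.inf, float(np.nanmean(s2[ok])) if ok.any() else 1.0
    s2 = s2[ok]
    df = df[ok]
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0 = np.exp(emean)
    return float(d0), float(s0)


def moderated_ttest(
    m: ExpressionMatrix,
    meta: pd.DataFrame,
    group_a: str,
    group_b: str,
    prior_df: Optional[float] = None,
    max_missing_fraction: float = 0.5,
) -> DEResult:
    """Moderated two-sample t-test between ``group_a`` and ``group_b``.

    ``prior_df`` overrides the estimated prior degrees of freedom
    (0 gives the classical pooled t; numpy.inf gives fully pooled
    variance). Probes missing in more than ``max_missing_fraction`` of
    either group's samples (or with fewer than two observations in a
    group) are excluded from testing and from the Holm adjustment count.
    """
    if m.scale != "log2":
        raise ValueError("moderated_ttest expects a log2-scale matrix")
    cols_a = [s for s in m.sample_ids if s in set(meta.loc[meta["group"] == group_a, "sample_id"])]
    cols_b = [s for s in m.sample_ids if s in set(meta.loc[meta["group"] == group_b, "sample_id"])]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(f"need >=2 samples per group ({group_a!r}: {len(cols_a)}, {group_b!r}: {len(cols_b)})")

    A = m.data[cols_a].to_numpy(dtype=float)
    B = m.data[cols_b].to_numpy(dtype=float)
    na = np.sum(np.isfinite(A), axis=1)
    nb = np.sum(np.isfinite(B), axis=1)
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows excluded below
        mean_a = np.nanmean(np.where(np.isfinite(A), A, np.nan), axis=1)
        mean_b = np.nanmean(np.where(np.isfinite(B), B, np.nan), axis=1)
        var_a = _nanvar(A, na)
        var_b = _nanvar(B, nb)

    present_a = na / len(cols_a)
    present_b = nb / len(cols_b)
    valid = (na >= 2) & (nb >= 2) & (present_a >= 1 - max_missing_fraction) & (present_b >= 1 - max_missing_fraction)

    d = (na + nb - 2).astype(float)
    s2 = np.full(len(d), np.nan)
    with np.errstate(invalid="ignore"):
        s2[valid] = ((na - 1) * var_a + (nb - 1) * var_b)[valid] / d[valid]

    if prior_df is None:
        d0, s02 = _fit_variance_prior(s2[valid], d[valid])
    else:
        d0 = float(prior_df)
        _, s02 = _fit_variance_prior(s2[valid], d[valid])

    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
    elif d0 == 0:
        s2_post = s2.copy()
    else:
        s2_post = (d0 * s02 + d * s2) / (d0 + d)

    delta = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
        t = delta / se
    df_total = d0 + d
    p = np.full(len(t), np.nan)
    finite_df = np.isfinite(df_total)
    with np.errstate(invalid="ignore"):
        p[valid & finite_df] = 2.0 * stats.t.sf(np.abs(t[valid & finite_df]), df_total[valid & finite_df])
        inf_df = valid & ~finite_df
        p[inf_df] = 2.0 * stats.norm.sf(np.abs(t[inf_df]))
    # equal means with zero posterior variance: define t = 0, p = 1
    degenerate = valid & (delta == 0) & ~np.isfinite(t)
    t[degenerate] = 0.0
    p[degenerate] = 1.0

    p_holm = np.full(len(p), np.nan)
    tested = valid & np.isfinite(p)
    if tested.any():
        p_holm[tested] = holm_adjust(p[tested])

    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": delta,
            "t_mod": t,
            "df_total": df_total,
            "p_raw": p,
            "p_holm": p_holm,
            "excluded": ~valid,
        },
        index=m.probe_ids,
    )
    return DEResult(table, group_a, group_b, float(d0), float(s02))


def _nanvar(X: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Row-wise unbiased variance ignoring NaN; NaN where n < 2."""
    out = np.full(X.shape[0], np.nan)
    ok = n >= 2
    if ok.any():
        with np.errstate(invalid="ignore"):
            mu = np.nanmean(X[ok], axis=1, keepdims=True)
            sq = np.nansum((X[ok] - mu) ** 2, axis=1)
            out[ok] = sq / (n[ok] - 1)
    return out


def holm_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order.

    p_(i) is multiplied by (m - i + 1), made monotone nondecreasing by a
    cumulative maximum over the sorted order, and capped at 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def select_significant(
    de: DEResult, alpha: float = 0.05, use_adjusted: bool = False
) -> list:
    """Probes with (raw or Holm-adjusted) p strictly below ``alpha``."""
    col = "p_holm" if use_adjusted else "p_raw"
    mask = de.table[col] < alpha
    return list(de.table.index[mask.fillna(False)])


def concordance_analysis(
    de_a: DEResult, de_b: DEResult, alpha: float = 0.05, use_adjusted: bool = False
) -> ConcordanceResult:
    """Probes significant in both comparisons, with paired log2 ratios.

    Reports the number significant in comparison A alone (the denominator
    of a "selected of regulated" headline count) and the fraction of
    selected probes whose fold changes agree in sign between the two
    comparisons.
    """
    shared = de_a.table.index.intersection(de_b.table.index)
    if len(shared) == 0:
        raise ValueError("probe universes of the two comparisons are disjoint")
    col = "p_holm" if use_adjusted else "p_raw"
    ta = de_a.table.loc[shared]
    tb = de_b.table.loc[shared]
    sig_a = ta[col] < alpha
    sig_b = tb[col] < alpha
    both = (sig_a & sig_b).fillna(False)
    selected = list(shared[both])
    pairs = pd.DataFrame(
        {
            "log2ratio_a": ta.loc[both, "log2fc"],
            "log2ratio_b": tb.loc[both, "log2fc"],
        }
    )
    if len(pairs):
        agree = np.sign(pairs["log2ratio_a"]) == np.sign(pairs["log2ratio_b"])
        sign_agreement = float(agree.mean())
    else:
        sign_agreement = float("nan")
    return ConcordanceResult(
        selected=selected,
        pairs=pairs,
        n_regulated_in_a=int(sig_a.fillna(False).sum()),
        n_selected=len(selected),
        sign_agreement=sign_agreement,
    )


def ddct_relative_expression(
    qpcr: pd.DataFrame,
    target: str,
    reference: str,
    calibrator_samples: Sequence[str],
) -> pd.DataFrame:
    """Relative expression by the delta-delta-Ct method.

    dCt = Ct(target) - Ct(reference) per sample; ddCt subtracts the mean
    dCt of the calibrator samples; fold = 2^(-ddCt).
    """
    required = {"sample_id", "gene", "ct"}
    if not required.issubset(qpcr.columns):
        raise ValueError(f"qPCR table must have columns {sorted(required)}")
    wide = qpcr.pivot_table(index="sample_id", columns="gene", values="ct", aggfunc="mean")
    if reference not in wide.columns:
        raise ValueError(f"reference gene {reference!r} absent from table")
    if target not in wide.columns:
        raise ValueError(f"target gene {target!r} absent from table")
    missing_ref = wide.index[wide[reference].isna()]
    if len(missing_ref):
        raise ValueError(f"missing reference Ct for sample {missing_ref[0]!r}")
    has_target = wide[target].notna()
    dct = wide.loc[has_target, target] - wide.loc[has_target, reference]
    cal = [s for s in calibrator_samples if s in dct.index]
    if not cal:
        raise ValueError("no calibrator sample has both target and reference Ct")
    ddct = dct - dct.loc[cal].mean()
    fold = np.power(2.0, -ddct)
    return pd.DataFrame({"dct": dct, "ddct": ddct, "fold": fold})
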