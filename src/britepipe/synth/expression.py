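"""Synthetic bead-array experiments with known ground truth.

Baseline probe intensities are log-normal (log2 mean ~8, sd ~1.5),
matching a bead array's dynamic range so quantile normalization behaves
realistically. Planted probe blocks are shifted by the configured log2
effect size in their (group, timepoint) cells. Bead replicates scatter
multiplicatively around the probe mean with the configured CV, and a
configurable fraction of beads is spiked to 10x / 0.1x of its value so
that the 2.5-MAD outlier filter is exercised deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from ..config import SimConfig


@dataclass
class ExpressionTruth:
    """Ground truth of a synthetic expression experiment."""

    baseline_log2: pd.Series  # per probe
    expected_log2: pd.DataFrame  # probes x samples, baseline + planted shift
    probe_effects: Dict[str, Dict[Tuple[str, str], float]]  # probe -> (group, tp) -> shift
    signal_probes: Dict[str, List[str]]  # signal label -> probe ids
    planted_sets: Dict[str, dict] = field(default_factory=dict)  # filled by gen_gene_sets


def _sample_frame(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for group in cfg.groups:
        for tp in cfg.timepoints:
            for rep in range(1, cfg.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{group}_{tp}_r{rep}",
                        "group": group,
                        "timepoint": tp,
                        "ne_status": cfg.ne_status,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def gen_expression_experiment(
    cfg: SimConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, ExpressionTruth]:
    """Generate (bead-level table, sample metadata, ground truth).

    The bead table is long-format (probe_id, sample_id, bead_value); the
    metadata has one row per sample. Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    probes = np.array([f"G{i:05d}" for i in range(cfg.n_probes)])
    meta = _sample_frame(cfg)
    samples = meta["sample_id"].to_numpy()
    n_p, n_s = len(probes), len(samples)

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, n_p)

    # assign disjoint probe blocks to the planted signals
    shuffled = rng.permutation(n_p)
    shift = np.zeros((n_p, n_s))
    probe_effects: Dict[str, Dict[Tuple[str, str], float]] = {}
    signal_probes: Dict[str, List[str]] = {}
    cursor = 0
    cell_of_sample = list(zip(meta["group"], meta["timepoint"]))
    for sig in cfg.signals:
        idx = shuffled[cursor : cursor + sig.n_probes]
        cursor += sig.n_probes
        signal_probes[sig.label] = [probes[i] for i in idx]
        effect = sig.direction * cfg.effect_size
        cells = {(g, t) for g in sig.groups for t in sig.timepoints}
        col_mask = np.array([cell in cells for cell in cell_of_sample])
        shift[np.ix_(idx, col_mask)] += effect
        for i in idx:
            eff = probe_effects.setdefault(probes[i], {})
            for cell in cells:
                eff[cell] = eff.get(cell, 0.0) + effect

    expected = baseline[:, None] + shift
    truth = ExpressionTruth(
        baseline_log2=pd.Series(baseline, index=probes),
        expected_log2=pd.DataFrame(expected, index=probes, columns=samples),
        probe_effects=probe_effects,
        signal_probes=signal_probes,
    )

    # biological (within-group) noise per probe x sample, then beads
    mu = expected + rng.normal(0.0, cfg.noise_sd, (n_p, n_s))
    linear_mean = np.power(2.0, mu)
    nb = cfg.beads_per_probe
    beads = linear_mean[:, :, None] * (
        1.0 + cfg.bead_cv * rng.normal(size=(n_p, n_s, nb))
    )
    beads = np.clip(beads, 0.01, None)
    if cfg.outlier_rate > 0:
        out_mask = rng.random((n_p, n_s, nb)) < cfg.outlier_rate
        factors = np.where(rng.random((n_p, n_s, nb)) < 0.5, 10.0, 0.1)
        beads = np.where(out_mask, beads * factors, beads)

    table = pd.DataFrame(
        {
            "probe_id": np.repeat(probes, n_s * nb),
            "sample_id": np.tile(np.repeat(samples, nb), n_p),
            "bead_value": beads.ravel(),
        }
    )
    return table, meta, truth
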