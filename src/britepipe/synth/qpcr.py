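"""Synthetic qPCR plates with planted fold changes.

A planted fold change F in a treated group is encoded as a target-gene
Ct shift of -log2(F) relative to the calibrator group, so the
delta-delta-Ct method recovers F exactly on noiseless plates.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import pandas as pd

from ..config import SimConfig


def gen_qpcr_plate(cfg: SimConfig) -> Tuple[pd.DataFrame, Dict[str, Dict[str, float]]]:
    """Generate (Ct table, truth) for the configured targets.

    The table is long-format (sample_id, group, gene, ct) covering the
    reference gene and every target for ``cfg.n_replicates`` samples per
    group. Truth maps gene -> group -> planted fold (1.0 in the
    calibrator group). Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 3)
    groups = [g for g in cfg.groups if g in (cfg.qpcr_calibrator_group,)] + [
        g for g in cfg.groups if g != cfg.qpcr_calibrator_group
    ]
    base_ct = {cfg.qpcr_reference: 18.0}
    for i, gene in enumerate(cfg.qpcr_targets):
        base_ct[gene] = 24.0 + i  # typical low-abundance targets

    rows = []
    truth: Dict[str, Dict[str, float]] = {g: {} for g in cfg.qpcr_targets}
    for group in groups:
        for rep in range(1, cfg.n_replicates + 1):
            sample_id = f"{group}_q{rep}"
            rows.append(
                {
                    "sample_id": sample_id,
                    "group": group,
                    "gene": cfg.qpcr_reference,
                    "ct": base_ct[cfg.qpcr_reference]
                    + rng.normal(0.0, cfg.qpcr_ct_sd),
                }
            )
            for gene, fold in cfg.qpcr_targets.items():
                f = 1.0 if group == cfg.qpcr_calibrator_group else float(fold)
                truth[gene][group] = f
                rows.append(
                    {
                        "sample_id": sample_id,
                        "group": group,
                        "gene": gene,
                        "ct": base_ct[gene]
                        - np.log2(f)
                        + rng.normal(0.0, cfg.qpcr_ct_sd),
                    }
                )
    return pd.DataFrame(rows), truth
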