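"""Synthetic GMT gene-set collections with planted enriched sets.

One gene set is emitted per planted signal, drawn from that signal's
probes (so the set is genuinely enriched in the direction and at the
timepoints the signal was planted); the remaining sets are drawn
uniformly from the probe universe with sizes uniform over the configured
range.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np

from ..config import ConfigError, SimConfig
from ..gsea import GeneSet, GeneSetCollection
from .expression import ExpressionTruth


def gen_gene_sets(
    cfg: SimConfig, truth: Optional[ExpressionTruth] = None
) -> Tuple[GeneSetCollection, Dict[str, dict]]:
    """Generate (collection, planted labels).

    ``truth`` (from ``gen_expression_experiment``) supplies the planted
    probe blocks; without it all sets are unplanted random draws.
    Planted labels map set name -> {direction, timepoints, groups} and
    are also recorded on ``truth.planted_sets``.
    """
    cfg.validate()
    lo, hi = cfg.set_size_range
    if hi > cfg.n_probes:
        raise ConfigError("set size exceeds n_probes")
    rng = np.random.default_rng(cfg.seed + 1)
    probes = np.array([f"G{i:05d}" for i in range(cfg.n_probes)])

    sets = []
    planted: Dict[str, dict] = {}
    if truth is not None:
        sig_by_label = {s.label: s for s in cfg.signals}
        for label, members in truth.signal_probes.items():
            if len(sets) >= cfg.n_sets:  # n_sets is the collection total
                break
            sig = sig_by_label[label]
            size = min(len(members), hi)
            chosen = list(rng.choice(members, size=size, replace=False))
            if size < lo:  # pad with unplanted probes to reach the minimum
                pool = np.setdiff1d(probes, np.array(chosen))
                chosen += list(rng.choice(pool, size=lo - size, replace=False))
            name = f"SET_{label.upper()}"
            sets.append(GeneSet(name, f"planted {label} signal", tuple(chosen)))
            planted[name] = {
                "direction": "up" if sig.direction > 0 else "down",
                "timepoints": list(sig.timepoints),
                "groups": list(sig.groups),
            }
    n_random = max(cfg.n_sets - len(sets), 0)
    for k in range(n_random):
        size = int(rng.integers(lo, hi + 1))
        members = tuple(rng.choice(probes, size=size, replace=False))
        sets.append(GeneSet(f"SET_RANDOM_{k:03d}", "random set", members))
    collection = GeneSetCollection(sets)
    if truth is not None:
        truth.planted_sets = planted
    return collection, planted
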