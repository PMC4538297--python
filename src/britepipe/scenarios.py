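"""Reference benchmark scenarios exercising the pipeline on known truth.

These fix the synthetic study conditions used for calibration and
recovery benchmarks: bead-array experiments at 3 replicates per group
with KEGG-scale gene sets (80-160 genes, the size range of the strongly
enriched pathways such benchmarks emulate), planted coordinated shifts
of one within-group standard deviation, and the differentiation
time-course schedule in which progenitor-activation signals (cell cycle
up, adhesion down at 24 h) precede metabolic maturation (OxPhos program
up at the late timepoints).
"""

from __future__ import annotations

from typing import Dict, Tuple

from .beadarray import log2_transform, quantile_normalize, summarize_table
from .config import PlantedSignal, SimConfig
from .synth import gen_expression_experiment, gen_gene_sets

TRAJECTORY_TIMEPOINTS = ("0h", "24h", "2d", "4d", "6d", "8d")

# planted (set, timepoint) -> scheduled ES sign
TRAJECTORY_SCHEDULE: Dict[Tuple[str, str], int] = {
    ("SET_PROLIFERATION", "24h"): +1,
    ("SET_ADHESION", "24h"): -1,
    ("SET_OXPHOS", "4d"): +1,
    ("SET_OXPHOS", "6d"): +1,
    ("SET_OXPHOS", "8d"): +1,
}


def gsea_planted_config(seed: int) -> SimConfig:
    """One 100-gene set shifted +1 within-group SD, 3 vs 3 at one timepoint."""
    return SimConfig(
        n_probes=1000,
        n_sets=15,
        set_size_range=(80, 160),
        groups=("Control", "cPGI2"),
        timepoints=("8d",),
        noise_sd=0.25,
        effect_size=0.25,  # +1 SD in within-group log2 noise units
        signals=(PlantedSignal("up", 100, ("cPGI2",), ("8d",), +1),),
        seed=seed,
    )


def gsea_null_config(seed: int) -> SimConfig:
    """Same design with no planted effect."""
    return SimConfig(
        n_probes=1000,
        n_sets=15,
        set_size_range=(80, 160),
        groups=("Control", "cPGI2"),
        timepoints=("8d",),
        noise_sd=0.25,
        effect_size=0.0,
        signals=(),
        seed=seed,
    )


def trajectory_config(seed: int) -> SimConfig:
    """Differentiation schedule: activation at 24 h, maturation late."""
    return SimConfig(
        n_probes=1000,
        n_sets=15,
        set_size_range=(80, 160),
        groups=("Control", "cPGI2"),
        timepoints=TRAJECTORY_TIMEPOINTS,
        noise_sd=0.25,
        effect_size=0.25,
        signals=(
            PlantedSignal("proliferation", 100, ("cPGI2",), ("24h",), +1),
            PlantedSignal("adhesion", 100, ("cPGI2",), ("24h",), -1),
            PlantedSignal("oxphos", 100, ("cPGI2",), ("4d", "6d", "8d"), +1),
        ),
        seed=seed,
    )


def expression_pipeline(cfg: SimConfig):
    """Generate and preprocess one experiment.

    Returns (log2 matrix, metadata, gene-set collection, truth) after the
    full bead-level path: summarize -> quantile normalize -> log2.
    """
    beads, meta, truth = gen_expression_experiment(cfg)
    collection, _ = gen_gene_sets(cfg, truth)
    matrix = log2_transform(quantile_normalize(summarize_table(beads)))
    return matrix, meta, collection, truth
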