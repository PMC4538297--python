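"""Study-design configuration for the synthetic experiment generators.

The defaults emulate a beige/brite differentiation study on Illumina
bead arrays: three culture conditions (Control "white", cPGI2-treated,
and brown-fat BAT reference), three biological replicates per group,
a differentiation time course from 0 h to day 8, and 3D DNA-FISH
imaging of a diploid gene locus (two alleles per nucleus) at
controlled radial positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Tuple


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class PlantedSignal:
    """A block of co-regulated probes shifted in specific (group, timepoint) cells.

    ``direction`` is +1 (up in ``groups`` relative to everyone else) or -1.
    The shift magnitude comes from ``SimConfig.effect_size`` (log2 units).
    """

    label: str
    n_probes: int
    groups: Tuple[str, ...]
    timepoints: Tuple[str, ...]
    direction: int = 1


@dataclass(frozen=True)
class ImageParams:
    """Geometry and optics of the synthetic 3D-FISH fields.

    Voxels are anisotropic on purpose: 100 nm in xy, 200 nm z-step
    (the acquisition interval of the emulated microscope), so downstream
    code must treat z in physical units.
    """

    frame_shape: Tuple[int, int, int] = (16, 96, 96)  # (z, y, x)
    xy_nm: float = 100.0
    z_step_nm: float = 200.0
    semi_axes_xy: Tuple[float, float] = (18.0, 13.0)  # nucleus semi-axes, px
    semi_axis_z: float = 5.0  # in z-slices
    psf_sigma: float = 1.0  # lateral PSF sigma, px (axial scaled by xy/z ratio)
    nucleus_intensity: float = 400.0
    spot_intensity: float = 3000.0
    background: float = 100.0
    n_chromocenters: int = 6
    chromocenter_intensity: float = 2000.0
    noise_read_sd: float = 3.0
    poisson_noise: bool = True
    n_probe_channels: int = 1
    spots_per_probe: int = 2  # diploid locus: two alleles
    nuclei_per_field: int = 1
    random_rotation: bool = True


def _default_signals() -> Tuple[PlantedSignal, ...]:
    # Mirrors the study's kinetics: progenitor activation (cell cycle up,
    # adhesion down) at 24 h precedes metabolic maturation (OxPhos /
    # thermogenic program up at late timepoints, shared with BAT).
    return (
        PlantedSignal("proliferation", 40, ("cPGI2",), ("24h",), +1),
        PlantedSignal("adhesion", 40, ("cPGI2",), ("24h",), -1),
        PlantedSignal("oxphos", 40, ("cPGI2", "BAT"), ("4d", "6d", "8d"), +1),
    )


@dataclass
class SimConfig:
    """All knobs for the synthetic expression / imaging / qPCR generators."""

    # expression design
    n_probes: int = 1000
    n_sets: int = 25
    set_size_range: Tuple[int, int] = (15, 160)
    groups: Tuple[str, ...] = ("Control", "cPGI2", "BAT")
    n_replicates: int = 3
    timepoints: Tuple[str, ...] = ("0h", "24h", "2d", "4d", "6d", "8d")
    ne_status: str = "-NE"
    effect_size: float = 1.0  # log2 shift of planted probes
    noise_sd: float = 0.25  # within-group biological SD, log2
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    beads_per_probe: int = 20
    bead_cv: float = 0.08  # coefficient of variation of bead replicates
    outlier_rate: float = 0.01  # fraction of beads spiked 10x / 0.1x
    signals: Tuple[PlantedSignal, ...] = field(default_factory=_default_signals)

    # FISH imaging design: shell placement probabilities per condition
    # (central, intermediate, peripheral). cPGI2 central fraction mirrors
    # the treated-adipocyte localization; Control is peripheral-dominant.
    fish_shell_probs: Mapping[str, Tuple[float, float, float]] = field(
        default_factory=lambda: {
            "Control": (0.15, 0.35, 0.50),
            "cPGI2": (0.433, 0.35, 0.217),
        }
    )
    n_nuclei: int = 40  # per condition; study analyzed 30-50 per experiment
    image: ImageParams = field(default_factory=ImageParams)

    # qPCR design: fold changes of target genes in each non-calibrator group
    qpcr_targets: Mapping[str, float] = field(
        default_factory=lambda: {"Ucp1": 16.0, "Cidea": 4.0}
    )
    qpcr_reference: str = "Tbp"
    qpcr_calibrator_group: str = "Control"
    qpcr_ct_sd: float = 0.1

    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_probes <= 0:
            raise ConfigError("n_probes must be > 0")
        if self.n_sets < 0:
            raise ConfigError("n_sets must be >= 0")
        lo, hi = self.set_size_range
        if not (1 <= lo <= hi <= self.n_probes):
            raise ConfigError(
                f"set_size_range {self.set_size_range} must lie within [1, n_probes={self.n_probes}]"
            )
        if self.n_replicates <= 0:
            raise ConfigError("n_replicates must be > 0")
        if not self.groups or not self.timepoints:
            raise ConfigError("groups and timepoints must be non-empty")
        if len(set(self.groups)) != len(self.groups):
            raise ConfigError("duplicate group labels")
        if self.beads_per_probe <= 0:
            raise ConfigError("beads_per_probe must be > 0")
        if not (0.0 <= self.outlier_rate <= 1.0):
            raise ConfigError("outlier_rate must be in [0, 1]")
        if self.bead_cv < 0 or self.noise_sd < 0 or self.qpcr_ct_sd < 0:
            raise ConfigError("noise parameters must be >= 0")
        planted = sum(s.n_probes for s in self.signals)
        if planted > self.n_probes:
            raise ConfigError("planted signal probes exceed n_probes")
        for sig in self.signals:
            for g in sig.groups:
                if g not in self.groups:
                    raise ConfigError(f"signal {sig.label!r}: unknown group {g!r}")
            for t in sig.timepoints:
                if t not in self.timepoints:
                    raise ConfigError(f"signal {sig.label!r}: unknown timepoint {t!r}")
            if sig.direction not in (+1, -1):
                raise ConfigError(f"signal {sig.label!r}: direction must be +-1")
        for cond, probs in self.fish_shell_probs.items():
            if len(probs) != 3 or any(p < 0 or p > 1 for p in probs):
                raise ConfigError(f"shell probabilities for {cond!r} must be 3 values in [0,1]")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigError(f"shell probabilities for {cond!r} must sum to 1")
        if self.n_nuclei <= 0:
            raise ConfigError("n_nuclei must be > 0")
        img = self.image
        a, b = img.semi_axes_xy
        zdim, ydim, xdim = img.frame_shape
        margin = 2.0
        if 2 * a + margin >= xdim or 2 * b + margin >= ydim or 2 * img.semi_axis_z >= zdim:
            raise ConfigError("nucleus larger than image frame")
        if self.qpcr_reference in self.qpcr_targets:
            raise ConfigError("reference gene cannot also be a target")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fish_shell_probs"] = {k: list(v) for k, v in self.fish_shell_probs.items()}
        d["qpcr_targets"] = dict(self.qpcr_targets)
        return d


def config_from_dict(d: Mapping) -> SimConfig:
    """Rebuild a SimConfig from a plain mapping (e.g. parsed YAML)."""
    d = dict(d)
    if "image" in d and isinstance(d["image"], Mapping):
        img = dict(d["image"])
        for key in ("frame_shape", "semi_axes_xy"):
            if key in img:
                img[key] = tuple(img[key])
        d["image"] = ImageParams(**img)
    if "signals" in d:
        sigs = []
        for s in d["signals"]:
            if isinstance(s, Mapping):
                s = dict(s)
                s["groups"] = tuple(s["groups"])
                s["timepoints"] = tuple(s["timepoints"])
                sigs.append(PlantedSignal(**s))
            else:
                sigs.append(s)
        d["signals"] = tuple(sigs)
    for key in ("groups", "timepoints", "set_size_range"):
        if key in d and not isinstance(d[key], tuple):
            d[key] = tuple(d[key])
    if "fish_shell_probs" in d:
        d["fish_shell_probs"] = {k: tuple(v) for k, v in d["fish_shell_probs"].items()}
    return SimConfig(**d).validate()

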