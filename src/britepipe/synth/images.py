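"""Synthetic 3D DNA-FISH fields with known nucleus masks and spot truth.

Each field holds one (or a small grid of) ellipsoidal nuclei rendered in
a DAPI channel with bright chromocenter blobs (distractors that never
appear in the probe channels), plus one or two probe channels carrying
at most two allele spots each per nucleus (diploid locus). Voxels are
anisotropic (100 nm xy, 200 nm z-step).

Spot placement: a shell (central / intermediate / peripheral) is sampled
from the condition's placement probabilities, then a pixel is drawn
uniformly from that shell's region of the true footprint — the shell
regions being the same equal-area distance-transform bands the analysis
pipeline uses, so the configured probabilities are the exact expected
shell fractions. Spot centers sit on integer voxels. A Gaussian PSF blur
and Poisson + Gaussian read noise are applied unless disabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from ..config import ConfigError, SimConfig
from ..fish import VoxelStack, equal_area_shells


@dataclass
class TrueNucleus:
    nucleus_id: int
    condition: str
    field_index: int
    center: Tuple[float, float, float]  # (z, y, x)
    semi_axes: Tuple[float, float, float]  # (z, y, x)
    rotation_deg: float
    footprint: np.ndarray  # 2D bool, full-frame
    spots: List[dict] = field(default_factory=list)  # channel, z, y, x, shell

    def to_json(self) -> dict:
        return {
            "nucleus_id": self.nucleus_id,
            "condition": self.condition,
            "field_index": self.field_index,
            "center": list(self.center),
            "semi_axes": list(self.semi_axes),
            "rotation_deg": self.rotation_deg,
            "spots": self.spots,
        }


@dataclass
class ImageTruth:
    nuclei: List[TrueNucleus]

    def spots_for(self, condition: str) -> List[dict]:
        return [s for n in self.nuclei if n.condition == condition for s in n.spots]

    def to_json(self) -> dict:
        return {"nuclei": [n.to_json() for n in self.nuclei]}


def _ellipse_footprint(shape, cy, cx, a_y, a_x, theta) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy, dx = yy - cy, xx - cx
    c, s = np.cos(theta), np.sin(theta)
    u = (dx * c + dy * s) / a_x
    v = (-dx * s + dy * c) / a_y
    return u**2 + v**2 <= 1.0


def _ellipsoid_mask(shape, center, axes, theta) -> np.ndarray:
    zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    dz, dy, dx = zz - center[0], yy - center[1], xx - center[2]
    c, s = np.cos(theta), np.sin(theta)
    u = (dx * c + dy * s) / axes[2]
    v = (-dx * s + dy * c) / axes[1]
    w = dz / axes[0]
    return u**2 + v**2 + w**2 <= 1.0


def render_field(
    cfg: SimConfig,
    condition: str,
    rng: np.random.Generator,
    field_index: int = 0,
    nucleus_id_start: int = 1,
    n_nuclei: Optional[int] = None,
) -> Tuple[VoxelStack, List[TrueNucleus]]:
    """Render one multi-channel field with ``n_nuclei`` nuclei."""
    img = cfg.image
    zdim, ydim, xdim = img.frame_shape
    n_nuclei = n_nuclei if n_nuclei is not None else img.nuclei_per_field
    probs = np.asarray(cfg.fish_shell_probs[condition], dtype=float)
    n_ch = 1 + img.n_probe_channels
    data = np.full((n_ch, zdim, ydim, xdim), img.background, dtype=float)
    channels = {"dapi": 0}
    for p in range(img.n_probe_channels):
        channels[f"probe{p + 1}"] = p + 1

    a_y, a_x = img.semi_axes_xy[1], img.semi_axes_xy[0]
    a_z = img.semi_axis_z
    if 2 * a_x + 4 >= xdim or 2 * a_y + 4 >= ydim:
        raise ConfigError("nucleus larger than frame")

    # nucleus centers: single centered nucleus, or a jittered grid
    centers = []
    if n_nuclei == 1:
        centers.append((zdim / 2.0, ydim / 2.0, xdim / 2.0))
    else:
        cols = int(np.ceil(np.sqrt(n_nuclei)))
        rows_n = int(np.ceil(n_nuclei / cols))
        for k in range(n_nuclei):
            r, c = divmod(k, cols)
            cy = (r + 0.5) * ydim / rows_n + rng.uniform(-1, 1)
            cx = (c + 0.5) * xdim / cols + rng.uniform(-1, 1)
            centers.append((zdim / 2.0, cy, cx))

    truths: List[TrueNucleus] = []
    for k, (cz, cy, cx) in enumerate(centers):
        theta = rng.uniform(0, np.pi) if img.random_rotation else 0.0
        body = _ellipsoid_mask(img.frame_shape, (cz, cy, cx), (a_z, a_y, a_x), theta)
        data[0][body] += img.nucleus_intensity
        footprint = _ellipse_footprint((ydim, xdim), cy, cx, a_y, a_x, theta)
        shells = equal_area_shells(footprint, n_shells=3)

        # chromocenters: DAPI-bright blobs strictly inside the nucleus,
        # never rendered in the probe channels
        interior = ndimage.binary_erosion(footprint, iterations=3)
        int_idx = np.flatnonzero(interior.ravel())
        for _ in range(img.n_chromocenters):
            if int_idx.size == 0:
                break
            pix = int(rng.choice(int_idx))
            py, px = divmod(pix, xdim)
            pz = int(round(cz + rng.integers(-1, 2)))
            pz = int(np.clip(pz, 0, zdim - 1))
            data[0, pz, py, px] += img.chromocenter_intensity

        nucleus = TrueNucleus(
            nucleus_id=nucleus_id_start + k,
            condition=condition,
            field_index=field_index,
            center=(cz, cy, cx),
            semi_axes=(a_z, a_y, a_x),
            rotation_deg=float(np.degrees(theta)),
            footprint=footprint,
        )

        c, s = np.cos(theta), np.sin(theta)
        for p in range(img.n_probe_channels):
            ch_name = f"probe{p + 1}"
            for _allele in range(img.spots_per_probe):
                shell = int(rng.choice(3, p=probs)) + 1
                region = np.flatnonzero((shells.labels == shell).ravel())
                pix = int(rng.choice(region))
                sy, sx = divmod(pix, xdim)
                # z uniform within the ellipsoid chord at this (x, y)
                dx, dy = sx - cx, sy - cy
                u = ((dx * c + dy * s) / a_x) ** 2 + ((-dx * s + dy * c) / a_y) ** 2
                zmax = a_z * np.sqrt(max(1.0 - u, 0.0)) * 0.8
                sz = int(round(cz + rng.uniform(-zmax, zmax)))
                sz = int(np.clip(sz, 0, zdim - 1))
                data[p + 1, sz, sy, sx] += img.spot_intensity
                nucleus.spots.append(
                    {"channel": ch_name, "z": sz, "y": sy, "x": sx, "shell": shell}
                )
        truths.append(nucleus)

    if img.psf_sigma > 0:
        sigma_z = img.psf_sigma * img.xy_nm / img.z_step_nm
        for ch in range(n_ch):
            data[ch] = ndimage.gaussian_filter(
                data[ch], sigma=(sigma_z, img.psf_sigma, img.psf_sigma)
            )
    if img.poisson_noise:
        data = rng.poisson(np.clip(data, 0, None)).astype(float)
    if img.noise_read_sd > 0:
        data = data + rng.normal(0.0, img.noise_read_sd, data.shape)
    stack = VoxelStack(
        data=data.astype(np.float32),
        channels=channels,
        xy_nm=img.xy_nm,
        z_nm=img.z_step_nm,
    )
    return stack, truths


def gen_nucleus_images(
    cfg: SimConfig, conditions: Optional[Sequence[str]] = None
) -> Tuple[List[VoxelStack], ImageTruth]:
    """Generate ``cfg.n_nuclei`` one-nucleus fields per condition.

    Returns the stacks (ordered by condition, then nucleus) and the
    ground truth with per-nucleus masks and per-spot true shell labels.
    Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    conditions = list(conditions) if conditions is not None else list(cfg.fish_shell_probs)
    for cond in conditions:
        if cond not in cfg.fish_shell_probs:
            raise ConfigError(f"no shell probabilities configured for {cond!r}")
    rng = np.random.default_rng(cfg.seed + 2)
    stacks: List[VoxelStack] = []
    nuclei: List[TrueNucleus] = []
    nid = 1
    fidx = 0
    for cond in conditions:
        for _ in range(cfg.n_nuclei):
            stack, truths = render_field(
                cfg, cond, rng, field_index=fidx, nucleus_id_start=nid
            )
            stacks.append(stack)
            nuclei.extend(truths)
            nid += len(truths)
            fidx += 1
    return stacks, ImageTruth(nuclei)
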