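"""Synthetic pelvis-like CT phantom and pseudo-X-ray generator.

Real CT/X-ray pairs for this pipeline are patient data and cannot ship
with the package, so every stage is exercised on a parametric phantom:
an air background, a soft-tissue ellipsoid (torso), and bright bone
primitives — two "iliac wing" ellipsoids, a "sacrum", a pelvic-ring
torus and two femoral cylinders — with additive Gaussian HU noise.  The
left wing is deliberately enlarged: a left-right symmetric phantom would
make ±θ indistinguishable in projection and invalidate pose-recovery
tests for spurious reasons.

The pseudo-X-ray is a DRR rendered at a known ground-truth angle θ* and
pushed through a monotone gamma distortion, Gaussian blur and additive
noise, emulating the CR/DX modality gap between a real radiograph and a
maximum-intensity DRR without modelling scatter or beam hardening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging_io import HU_MAX, HU_MIN, CTVolume, Image2D
from .projection import mip_project, resample_isotropic, rotate_volume
from .segmentation import BinaryMask3D

__all__ = [
    "Ellipsoid",
    "ZCylinder",
    "TorusArc",
    "PhantomSpec",
    "XraySimSpec",
    "make_phantom",
    "make_phantom_with_masks",
    "make_reference_xray",
]


@dataclass
class Ellipsoid:
    """Axis-aligned ellipsoid; coordinates as fractions of the grid shape."""

    center: tuple[float, float, float]  # (z, y, x) fractions
    semi: tuple[float, float, float]
    tissue: str = "bone"

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        nz, ny, nx = shape
        z, y, x = np.ogrid[:nz, :ny, :nx]
        cz, cy, cx = (c * n for c, n in zip(self.center, shape))
        az, ay, ax = (s * n for s, n in zip(self.semi, shape))
        return ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2 <= 1.0


@dataclass
class ZCylinder:
    """Cylinder along z between fractional slice bounds."""

    z_range: tuple[float, float]
    center_yx: tuple[float, float]
    radius: float
    tissue: str = "bone"

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        nz, ny, nx = shape
        z, y, x = np.ogrid[:nz, :ny, :nx]
        cy, cx = self.center_yx[0] * ny, self.center_yx[1] * nx
        r = self.radius * min(ny, nx)
        z0, z1 = self.z_range[0] * nz, self.z_range[1] * nz
        return (z >= z0) & (z <= z1) & ((y - cy) ** 2 + (x - cx) ** 2 <= r**2)


@dataclass
class TorusArc:
    """Torus with its ring in an axial (x-y) plane; full ring by default."""

    center: tuple[float, float, float]
    ring_radius: float
    tube_radius: float
    tissue: str = "bone"

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        nz, ny, nx = shape
        z, y, x = np.ogrid[:nz, :ny, :nx]
        cz, cy, cx = (c * n for c, n in zip(self.center, shape))
        R = self.ring_radius * min(ny, nx)
        r = self.tube_radius * min(ny, nx)
        rho = np.sqrt((y - cy) ** 2 + (x - cx) ** 2)
        return (rho - R) ** 2 + (z - cz) ** 2 <= r**2


def _default_structures() -> list:
    f = 1.0 / 128.0  # designed on a 128-voxel reference grid
    return [
        Ellipsoid((64 * f, 64 * f, 64 * f), (58 * f, 46 * f, 54 * f), tissue="soft"),
        # left iliac wing, enlarged for left-right asymmetry
        Ellipsoid((48 * f, 58 * f, 34 * f), (26 * f, 14 * f, 18 * f)),
        Ellipsoid((48 * f, 58 * f, 94 * f), (20 * f, 11 * f, 13 * f)),  # right iliac wing
        Ellipsoid((52 * f, 78 * f, 64 * f), (18 * f, 9 * f, 11 * f)),  # sacrum
        TorusArc((74 * f, 64 * f, 64 * f), 26 * f, 5 * f),  # pelvic ring
        ZCylinder((92 * f, 1.0), (66 * f, 42 * f), 7 * f),  # left femur
        ZCylinder((92 * f, 1.0), (66 * f, 86 * f), 7 * f),  # right femur
    ]


@dataclass
class PhantomSpec:
    """Parameters of the synthetic CT.

    HU means follow clinical strata: air −1000, soft tissue ~40,
    trabecular/cortical bone ~1200.  ``noise_sd`` (default 30 HU) is a
    typical quantum-noise level for an abdominal CT reconstruction.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    hu_air: float = -1000.0
    hu_soft: float = 40.0
    hu_bone: float = 1200.0
    noise_sd: float = 30.0
    structures: list | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hu_air < self.hu_soft < self.hu_bone:
            raise ValueError("require hu_air < hu_soft < hu_bone")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(n < 32 for n in self.shape):
            raise ValueError("each grid dimension must be >= 32")


@dataclass
class XraySimSpec:
    """Parameters of the pseudo-X-ray derived from the phantom.

    Defaults: ground-truth pose 5°, gamma 1.8 (film-like response), 2%
    additive noise, 1 px blur.
    """

    true_angle_deg: float = 5.0
    gamma: float = 1.8
    noise_sd: float = 0.02  # fraction of the [0,1] range
    blur_sigma_px: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_phantom_with_masks(spec: PhantomSpec | None = None) -> tuple[CTVolume, BinaryMask3D]:
    """Build the phantom plus its noise-free ground-truth bone mask."""
    if spec is None:
        spec = PhantomSpec()
    structures = spec.structures if spec.structures is not None else _default_structures()
    vol = np.full(spec.shape, spec.hu_air, dtype=float)
    bone = np.zeros(spec.shape, dtype=bool)
    hu_of = {"soft": spec.hu_soft, "bone": spec.hu_bone}
    for s in structures:
        m = s.mask(spec.shape)
        vol[m] = hu_of[s.tissue]
        if s.tissue == "bone":
            bone |= m
        else:
            bone &= ~m  # later soft structures carve earlier bone
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    vol = np.clip(vol, HU_MIN, HU_MAX)
    ct = CTVolume(vol, spec.spacing, superior_first=True, source_meta={"phantom_seed": spec.seed})
    return ct, BinaryMask3D(bone.astype(np.uint8), spec.spacing)


def make_phantom(spec: PhantomSpec | None = None) -> CTVolume:
    """Deterministic synthetic CT volume (see :class:`PhantomSpec`)."""
    return make_phantom_with_masks(spec)[0]


def make_reference_xray(vol: CTVolume, spec: XraySimSpec | None = None) -> Image2D:
    """Render a pseudo-X-ray of the volume at the ground-truth angle θ*.

    Chain: DRR at θ* → isotropic resampling → min-max normalisation to
    [0, 1] → gamma transform → Gaussian blur → additive Gaussian noise →
    clip to [0, 1].  Deterministic given ``spec.seed``.
    """
    if spec is None:
        spec = XraySimSpec()
    drr = mip_project(rotate_volume(vol, spec.true_angle_deg))
    img = resample_isotropic(drr).values
    lo, hi = img.min(), img.max()
    img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    img = img**spec.gamma
    if spec.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma_px)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return Image2D(np.clip(img, 0.0, 1.0))
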