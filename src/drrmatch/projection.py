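"""CT-to-DRR core: z-axis volume rotation and maximum-intensity projection.

A DRR here is a *parallel-ray maximum intensity projection*: the volume is
rotated in the axial plane by an angle θ about the craniocaudal (z) axis
and the maximum HU along the anteroposterior (y) axis is taken, producing
a coronal-like 2D view whose rows are CT slices (superior slice on top)
and whose columns are the in-plane columns of the volume.

Sign convention: positive θ rotates the axial content counterclockwise
when viewed from superior, with 0° the native AP orientation of the CT;
pass ``flip_sign=True`` to :func:`rotate_volume` for the opposite
handedness.  Out-of-domain samples are filled with −1000 HU (air).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging_io import CTVolume, Image2D

AIR_HU = -1000.0


@dataclass
class DRRImage:
    """A 2D projection tagged with its rotation angle (canonical [0, 360))."""

    image: Image2D
    angle_deg: float
    source_spacing: tuple[float, float]  # (dz, dx) mm for rows / columns

    def __post_init__(self) -> None:
        self.angle_deg = float(self.angle_deg) % 360.0


@dataclass
class ProjectionSeries:
    projections: list[DRRImage]
    base_angle: float
    step_deg: float

    def angles(self) -> list[float]:
        return [p.angle_deg for p in self.projections]


def rotate_volume(vol: CTVolume, theta_deg: float, *, order: int = 1, flip_sign: bool = False) -> CTVolume:
    """Rotate every axial slice in-plane by θ about the slice centre.

    Bilinear interpolation by default; ``order=0`` selects
    nearest-neighbour (used by the exact permutation oracles).  The output
    grid has the same shape; samples falling outside the input domain
    become air (−1000 HU).
    """
    if not math.isfinite(theta_deg):
        raise ValueError("rotation angle must be finite")
    if flip_sign:
        theta_deg = -theta_deg
    if theta_deg % 360.0 == 0.0:
        return CTVolume(vol.values.copy(), vol.spacing, vol.superior_first, dict(vol.source_meta))
    th = math.radians(theta_deg)
    c, s = math.cos(th), math.sin(th)
    # output (r, c) samples input at centre + R(-theta) @ (r - cy, c - cx)
    mat = np.array([[1.0, 0.0, 0.0], [0.0, c, s], [0.0, -s, c]])
    nz, ny, nx = vol.shape
    centre = np.array([0.0, (ny - 1) / 2.0, (nx - 1) / 2.0])
    offset = centre - mat @ centre
    out = ndimage.affine_transform(
        vol.values.astype(float), mat, offset=offset, order=order, mode="constant", cval=AIR_HU
    )
    meta = dict(vol.source_meta)
    meta["rotated_deg"] = meta.get("rotated_deg", 0.0) + theta_deg
    return CTVolume(out, vol.spacing, vol.superior_first, meta)


def mip_project(vol: CTVolume) -> DRRImage:
    """Maximum-intensity projection along the anteroposterior (y) axis.

    ``output[row=z, col=x] = max_y vol[z, y, x]``; row 0 is the most
    superior slice.
    """
    img = vol.values.max(axis=1)
    dz, _dy, dx = vol.spacing
    angle = float(vol.source_meta.get("rotated_deg", 0.0))
    return DRRImage(Image2D(img, pixel_spacing=(dz, dx)), angle, (dz, dx))


def mip_project_window(vol: CTVolume, z_start: int, z_stop: int) -> DRRImage:
    """MIP restricted to a contiguous z-slab (e.g. 30 slices around the guide)."""
    if not (0 <= z_start < z_stop <= vol.shape[0]):
        raise ValueError(f"invalid slab [{z_start}, {z_stop}) for {vol.shape[0]} slices")
    sub = CTVolume(vol.values[z_start:z_stop], vol.spacing, vol.superior_first, dict(vol.source_meta))
    return mip_project(sub)


def series_angles(base_deg: float, half_range_deg: float, step_deg: float) -> np.ndarray:
    """Nominal (un-canonicalized) angle ladder base±half_range inclusive."""
    if step_deg <= 0:
        raise ValueError("step must be positive")
    if half_range_deg < 0:
        raise ValueError("half-range must be >= 0")
    if half_range_deg > 0 and step_deg > 2 * half_range_deg:
        raise ValueError(f"step {step_deg} exceeds the full range {2 * half_range_deg}")
    n = int(round(2 * half_range_deg / step_deg)) + 1
    return base_deg - half_range_deg + step_deg * np.arange(n)


def generate_series(
    vol: CTVolume, base_deg: float, half_range_deg: float, step_deg: float, *, order: int = 1
) -> ProjectionSeries:
    """DRRs at every angle of the ladder ``base − half_range .. base + half_range``.

    Each projection is ``mip_project(rotate_volume(vol, θ))`` with the
    angle stored canonically in [0, 360); e.g. base 0°, half-range 15°
    yields 31 projections with limits 345° and 15°.
    """
    angles = series_angles(base_deg, half_range_deg, step_deg)
    # avoid duplicating 0° == 360° when the ladder spans the full circle
    if len(angles) > 1 and (angles[-1] - angles[0]) % 360.0 == 0.0:
        angles = angles[:-1]
    projections = [mip_project(rotate_volume(vol, float(a), order=order)) for a in angles]
    for p, a in zip(projections, angles):
        p.angle_deg = float(a) % 360.0
    return ProjectionSeries(projections, base_angle=float(base_deg) % 360.0, step_deg=float(step_deg))


def resample_isotropic(drr: DRRImage) -> Image2D:
    """Resample a DRR to square pixels at ``min(dz, dx)`` mm.

    CT row spacing (the slice increment dz) generally differs from the
    column spacing dx, so raw MIPs are anisotropic; registration and
    display require square pixels.  Bilinear interpolation; a DRR with
    unknown spacing passes through unchanged with a warning.
    """
    import logging

    from skimage.transform import resize

    if drr.source_spacing is None:
        logging.getLogger(__name__).warning("unknown source spacing: passing image through unresampled")
        return drr.image
    dz, dx = drr.source_spacing
    target = min(dz, dx)
    rows, cols = drr.image.shape
    new_shape = (int(round(rows * dz / target)), int(round(cols * dx / target)))
    if new_shape == (rows, cols):
        return Image2D(drr.image.values.copy(), pixel_spacing=(target, target))
    out = resize(drr.image.values, new_shape, order=1, mode="edge", anti_aliasing=False, preserve_range=True)
    return Image2D(out, pixel_spacing=(target, target))
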