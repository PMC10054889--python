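"""Bone segmentation: HU thresholding, seeded region growing, mask splitting, meshing.

Thresholding keeps a voxel with value ``v`` iff ``t1 < v <= t2`` — a
half-open interval.  (The strict lower bound and inclusive upper bound are
the only consistent reading of "minimum and maximum threshold values" for
a band-pass voxel test; the choice is visible at exactly the two boundary
HU values and is documented here once.)

Region growing uses 6-connectivity (face neighbours) and compares every
candidate voxel against the HU value of the *originating seed*, not a
running region mean: growth with a fixed reference is deterministic
regardless of visit order.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .imaging_io import CTVolume

# default bone window in HU; cancellous bone starts around +200, anything
# above 3000 is metal in practice
DEFAULT_BONE_RANGE = (200, 3000)

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class ThresholdRange:
    """A half-open HU band (t1, t2]."""

    t1: float
    t2: float

    def __post_init__(self) -> None:
        if not self.t1 < self.t2:
            raise ValueError(f"require t1 < t2, got ({self.t1}, {self.t2})")


@dataclass
class BinaryMask3D:
    values: np.ndarray  # uint8 {0,1}
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("mask must be 3D")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.values = self.values.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.values.sum())


@dataclass
class LabeledMask3D:
    values: np.ndarray  # small non-negative ints; 0 = background
    label_names: dict[int, str]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        labels = set(np.unique(self.values)) - {0}
        missing = labels - set(self.label_names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")


@dataclass
class TriangleMesh:
    """Triangle surface mesh; vertices in mm."""

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray  # (m, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face index out of range")
        if self.faces.size:
            f = self.faces
            if ((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])).any():
                raise ValueError("degenerate face with repeated vertex")


def threshold_mask(vol: CTVolume, rng: ThresholdRange | tuple[float, float]) -> BinaryMask3D:
    """Band-pass voxel classifier: foreground iff ``t1 < HU <= t2``."""
    if not isinstance(rng, ThresholdRange):
        rng = ThresholdRange(*rng)
    out = (vol.values > rng.t1) & (vol.values <= rng.t2)
    return BinaryMask3D(out.astype(np.uint8), vol.spacing)


def region_grow(vol: CTVolume, seeds: list[tuple[int, int, int]], tol: float) -> BinaryMask3D:
    """Seeded region growing under 6-connectivity.

    A voxel ``v`` joins the region grown from seed ``s`` iff it is
    face-connected to it through voxels all satisfying
    ``|HU(s) - HU(v)| <= tol``.  Regions from different seeds are unioned.
    """
    if not seeds:
        raise ValueError("empty seed list")
    if tol < 0:
        raise ValueError("tolerance must be >= 0")
    shape = vol.shape
    for s in seeds:
        if len(s) != 3 or any(not (0 <= int(c) < n) for c, n in zip(s, shape)):
            raise ValueError(f"seed {s} out of bounds for volume of shape {shape}")

    out = np.zeros(shape, dtype=np.uint8)
    vals = vol.values
    for s in seeds:
        s = tuple(int(c) for c in s)
        ref = vals[s]
        # admissible set for this seed; region = its connected component containing the seed
        admissible = np.abs(vals - ref) <= tol
        lab, _ = ndimage.label(admissible, structure=_FACE_STRUCT)
        out |= (lab == lab[s]).astype(np.uint8)
    return BinaryMask3D(out, vol.spacing)


def split_mask(mask: BinaryMask3D, names: list[str] | None = None) -> LabeledMask3D:
    """Split a binary mask into 6-connected components.

    Components are relabelled 1..k by descending voxel count; ``names``
    are assigned positionally (e.g. sacrum, left ilium, ...), otherwise
    components are auto-named ``component_k``.
    """
    if mask.count() == 0:
        raise ValueError("cannot split an empty mask")
    lab, n = ndimage.label(mask.values, structure=_FACE_STRUCT)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    # stable ordering: descending size, then ascending original label
    order = sorted(range(1, n + 1), key=lambda k: (-sizes[k - 1], k))
    relabel = np.zeros(n + 1, dtype=np.int32)
    for new, old in enumerate(order, start=1):
        relabel[old] = new
    out = relabel[lab]
    label_names: dict[int, str] = {}
    for k in range(1, n + 1):
        if names is not None and k - 1 < len(names):
            label_names[k] = names[k - 1]
        else:
            label_names[k] = f"component_{k}"
    return LabeledMask3D(out, label_names, mask.spacing)


def mesh_from_mask(mask: BinaryMask3D) -> TriangleMesh:
    """Extract a closed triangle surface from a binary mask via marching cubes.

    The mask is padded by one voxel of background so surfaces touching the
    grid boundary are still closed; the iso-surface sits at level 0.5 and
    vertex coordinates are scaled to mm by the voxel spacing.
    """
    if mask.count() == 0:
        raise ValueError("cannot mesh an empty mask")
    padded = np.pad(mask.values.astype(np.float32), 1)
    dz, dy, dx = mask.spacing
    verts, faces, _normals, _vals = measure.marching_cubes(padded, level=0.5, spacing=(dz, dy, dx))
    verts -= np.array([dz, dy, dx])  # undo the pad offset
    return TriangleMesh(verts, faces)


def save_mesh_stl(mesh: TriangleMesh, path: str) -> None:
    """Export a mesh as binary STL."""
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(path)
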