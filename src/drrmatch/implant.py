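"""Virtual iliosacral screw/guide: modelling, voxelization and fusion into CT.

The guide is modelled either as a parametric cylinder (entry point,
direction, length, radius — the clinically meaningful degrees of freedom)
or as a triangle mesh already posed in the volume's physical frame, as
exported from CAD.  Voxelization uses a voxel-centre membership test with
no partial-volume antialiasing, so a maximum-intensity projection of the
fused volume attains exactly ``fuse_hu`` over the screw footprint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_io import CTVolume
from .segmentation import BinaryMask3D, TriangleMesh

#: default HU written into the volume where the screw sits: bright like
#: surgical steel, but below the 16-bit signed ceiling
DEFAULT_FUSE_HU = 3000


@dataclass
class ScrewModel:
    """Cylindrical screw/guide, or a posed surface mesh.

    For ``kind='parametric_cylinder'`` the axis runs from ``entry_point``
    along ``direction`` (unit vector, physical (z, y, x) mm frame) for
    ``length`` mm with circular cross-section of ``radius`` mm.
    """

    kind: str = "parametric_cylinder"
    entry_point: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    length: float = 80.0
    radius: float = 3.25
    mesh: TriangleMesh | None = None
    fuse_hu: float = DEFAULT_FUSE_HU

    def __post_init__(self) -> None:
        if self.kind not in ("parametric_cylinder", "mesh"):
            raise ValueError(f"unknown screw kind {self.kind!r}")
        if self.kind == "parametric_cylinder":
            d = np.asarray(self.direction, dtype=float)
            if abs(np.linalg.norm(d) - 1.0) > 1e-9:
                raise ValueError("direction must have unit norm")
            if self.length <= 0 or self.radius <= 0:
                raise ValueError("length and radius must be positive")
        elif self.mesh is None:
            raise ValueError("kind='mesh' requires a mesh")


def _voxel_centers(vol: CTVolume) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    dz, dy, dx = vol.spacing
    nz, ny, nx = vol.shape
    z = np.arange(nz) * dz
    y = np.arange(ny) * dy
    x = np.arange(nx) * dx
    return np.meshgrid(z, y, x, indexing="ij")


def voxelize_screw(screw: ScrewModel, vol: CTVolume) -> BinaryMask3D:
    """Rasterise the screw onto the volume grid.

    A voxel is foreground iff its physical centre lies inside the cylinder
    (axial projection in ``[0, length]`` and radial distance ``<= radius``)
    or inside the mesh (even-odd ray test).

    Raises
    ------
    ValueError
        If the screw does not cover any voxel centre, with a geometric
        diagnostic.
    """
    if screw.kind == "parametric_cylinder":
        zc, yc, xc = _voxel_centers(vol)
        e = np.asarray(screw.entry_point, dtype=float)
        d = np.asarray(screw.direction, dtype=float)
        pz, py, px = zc - e[0], yc - e[1], xc - e[2]
        a = pz * d[0] + py * d[1] + px * d[2]  # axial coordinate
        r2 = (pz - a * d[0]) ** 2 + (py - a * d[1]) ** 2 + (px - a * d[2]) ** 2
        inside = (a >= 0.0) & (a <= screw.length) & (r2 <= screw.radius**2)
    else:
        inside = _mesh_inside_mask(screw.mesh.vertices, screw.mesh.faces, vol)
    if not inside.any():
        dz, dy, dx = vol.spacing
        nz, ny, nx = vol.shape
        extent = (nz * dz, ny * dy, nx * dx)
        raise ValueError(
            f"screw covers no voxel centre: entry {tuple(np.round(screw.entry_point, 2))}, "
            f"volume physical extent (z,y,x) = {tuple(np.round(extent, 2))} mm"
        )
    return BinaryMask3D(inside.astype(np.uint8), vol.spacing)


def _mesh_inside_mask(vertices: np.ndarray, faces: np.ndarray, vol: CTVolume) -> np.ndarray:
    """Even-odd point-in-mesh test on the volume's voxel-centre grid.

    One ray per (z, y) grid cell is cast along +x; a voxel centre is
    inside iff an odd number of triangle crossings lie beyond it.  The
    grid regularity lets all x-positions of a cell share one crossing
    list.  Triangles are clipped to their projected bounding boxes, so
    the cost is O(n_triangles * covered cells).
    """
    dz, dy, dx = vol.spacing
    nz, ny, nx = vol.shape
    tri = np.asarray(vertices, dtype=float)[np.asarray(faces)]
    # rays are nudged off the lattice so they cannot hit triangle edges
    # exactly (which would double-count crossings on shared edges)
    ez, ey = 1.000000173e-7 * dz, 1.000000391e-7 * dy
    crossings: dict[tuple[int, int], list[float]] = {}
    for (z1, y1, x1), (z2, y2, x2), (z3, y3, x3) in tri:
        det = (y2 - y3) * (z1 - z3) + (z3 - z2) * (y1 - y3)
        if det == 0.0:  # projects to a line: parallel to the ray plane
            continue
        iz0 = max(0, int(np.ceil(min(z1, z2, z3) / dz)) - 1)
        iz1 = min(nz - 1, int(np.floor(max(z1, z2, z3) / dz)) + 1)
        iy0 = max(0, int(np.ceil(min(y1, y2, y3) / dy)) - 1)
        iy1 = min(ny - 1, int(np.floor(max(y1, y2, y3) / dy)) + 1)
        for iz in range(iz0, iz1 + 1):
            pz = iz * dz + ez
            if not (min(z1, z2, z3) <= pz <= max(z1, z2, z3)):
                continue
            for iy in range(iy0, iy1 + 1):
                py = iy * dy + ey
                l1 = ((y2 - y3) * (pz - z3) + (z3 - z2) * (py - y3)) / det
                l2 = ((y3 - y1) * (pz - z3) + (z1 - z3) * (py - y3)) / det
                l3 = 1.0 - l1 - l2
                if l1 >= 0.0 and l2 >= 0.0 and l3 >= 0.0:
                    crossings.setdefault((iz, iy), []).append(l1 * x1 + l2 * x2 + l3 * x3)
    inside = np.zeros((nz, ny, nx), dtype=bool)
    xs = np.arange(nx) * dx
    for (iz, iy), cr in crossings.items():
        cr = np.sort(cr)
        beyond = len(cr) - np.searchsorted(cr, xs, side="right")
        inside[iz, iy] = (beyond % 2) == 1
    return inside


def fuse_screw(vol: CTVolume, screw_mask: BinaryMask3D, fuse_hu: float = DEFAULT_FUSE_HU) -> CTVolume:
    """Overwrite masked voxels with ``fuse_hu``; the input volume is untouched."""
    if screw_mask.shape != vol.shape:
        raise ValueError(f"mask shape {screw_mask.shape} != volume shape {vol.shape}")
    out = vol.values.copy()
    out[screw_mask.values.astype(bool)] = fuse_hu
    meta = dict(vol.source_meta)
    meta["fused_hu"] = float(fuse_hu)
    return CTVolume(out, vol.spacing, vol.superior_first, meta)


def load_screw_mesh(path: str, fuse_hu: float = DEFAULT_FUSE_HU) -> ScrewModel:
    """Load a posed STL guide; vertices are interpreted as mm in volume space."""
    import trimesh

    tm = trimesh.load_mesh(path)
    if tm.is_empty or len(tm.faces) == 0:
        raise ValueError(f"degenerate or unreadable STL: {path}")
    tm.merge_vertices()
    mesh = TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    return ScrewModel(kind="mesh", mesh=mesh, fuse_hu=fuse_hu)
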