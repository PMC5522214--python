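"""Reference-grid geometry: world/pixel conversion, slice binning, disc rasterization.

All node centers live in a right-handed world frame in millimetres.  The atlas
is a stack of axial slices indexed cranial-to-caudal; each slice is an
``n_y x n_x`` pixel raster with a single isotropic in-plane spacing.  Every
node is drawn as a 5-mm-diameter disc on the single atlas slice that contains
its center.

Conventions (fixed and tested):

* voxel indices are 0-based with half-open bins:
  ``col = floor((x - origin_x) / spacing)`` and likewise for rows and slices;
* a pixel belongs to a disc iff its *center* lies within the disc radius
  (pixel-center inclusion, not any-overlap);
* pixel (row, col) covers world ``[origin + idx*s, origin + (idx+1)*s)`` per
  axis, so its center sits at ``origin + (idx + 0.5)*s``;
* discs clipped at the grid border are silently truncated, never rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReferenceGrid",
    "WorldPoint",
    "DiscMask",
    "OutOfGridError",
    "world_to_pixel",
    "atlas_slice_index",
    "rasterize_disc",
]

#: A point in the reference patient frame, millimetres: (x, y, z).
WorldPoint = tuple[float, float, float]


class OutOfGridError(ValueError):
    """A world coordinate falls outside the reference grid extent."""


@dataclass(frozen=True)
class ReferenceGrid:
    """Voxel lattice of the reference CT onto which the atlas is drawn.

    Parameters
    ----------
    origin : world (x, y, z) of the corner of voxel (0, 0, 0), mm.  In-plane
        pixel ``(row, col)`` spans ``[origin + idx*s, origin + (idx+1)*s)``.
    in_plane_spacing : isotropic x/y pixel size, mm.
    atlas_slice_thickness : craniocaudal bin size of atlas slices, mm.
    n_x, n_y : pixels per axial slice (columns, rows).
    z_min, z_max : craniocaudal extent covered, mm (z grows caudally).
    """

    origin: WorldPoint = (0.0, 0.0, 0.0)
    in_plane_spacing: float = 1.0
    atlas_slice_thickness: float = 5.0
    n_x: int = 220
    n_y: int = 220
    z_min: float = 0.0
    z_max: float = 200.0

    def __post_init__(self) -> None:
        if self.in_plane_spacing <= 0:
            raise ValueError("in_plane_spacing must be > 0")
        if self.atlas_slice_thickness <= 0:
            raise ValueError("atlas_slice_thickness must be > 0")
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("n_x and n_y must be >= 1")
        if not self.z_max > self.z_min:
            raise ValueError("z_max must exceed z_min")

    @property
    def n_slices(self) -> int:
        """Number of atlas slices covering [z_min, z_max)."""
        return int(
            math.ceil((self.z_max - self.z_min) / self.atlas_slice_thickness)
        )

    @property
    def shape(self) -> tuple[int, int]:
        """(n_y, n_x) raster shape of one axial slice."""
        return (self.n_y, self.n_x)

    def pixel_center(self, row: int, col: int) -> tuple[float, float]:
        """World (x, y) of the center of pixel (row, col)."""
        s = self.in_plane_spacing
        return (self.origin[0] + (col + 0.5) * s, self.origin[1] + (row + 0.5) * s)

    def slice_center_z(self, slice_index: int) -> float:
        """World z of the center of an atlas slice."""
        return self.z_min + (slice_index + 0.5) * self.atlas_slice_thickness

    def contains(self, p: WorldPoint) -> bool:
        """True if *p* lies inside the grid's half-open extent on all axes."""
        x, y, z = p
        s = self.in_plane_spacing
        return (
            self.origin[0] <= x < self.origin[0] + self.n_x * s
            and self.origin[1] <= y < self.origin[1] + self.n_y * s
            and self.z_min <= z < self.z_max
        )


@dataclass(frozen=True)
class DiscMask:
    """Pixels covered by one rasterized node disc on a single atlas slice."""

    slice_index: int
    pixels: frozenset[tuple[int, int]] = field(default_factory=frozenset)


def world_to_pixel(p: WorldPoint, grid: ReferenceGrid) -> tuple[int, int]:
    """In-plane (row, col) bin of a world point, half-open 0-based bins.

    Raises :class:`OutOfGridError` naming the offending axis when the point
    lies outside the in-plane extent.
    """
    s = grid.in_plane_spacing
    col = math.floor((p[0] - grid.origin[0]) / s)
    row = math.floor((p[1] - grid.origin[1]) / s)
    if not 0 <= col < grid.n_x:
        raise OutOfGridError(f"x={p[0]} mm outside grid extent on axis x")
    if not 0 <= row < grid.n_y:
        raise OutOfGridError(f"y={p[1]} mm outside grid extent on axis y")
    return (row, col)


def atlas_slice_index(z: float, grid: ReferenceGrid) -> int:
    """Atlas slice containing craniocaudal coordinate *z* (half-open bins)."""
    if not grid.z_min <= z < grid.z_max:
        raise OutOfGridError(
            f"z={z} mm outside atlas extent [{grid.z_min}, {grid.z_max}) on axis z"
        )
    return math.floor((z - grid.z_min) / grid.atlas_slice_thickness)


def rasterize_disc(
    center: WorldPoint, diameter: float, grid: ReferenceGrid
) -> DiscMask:
    """Rasterize a node disc of the given diameter (mm) onto its atlas slice.

    A pixel is included iff its center lies at in-plane Euclidean distance
    <= diameter/2 from the disc center.  The disc contributes to exactly one
    slice — the one containing ``center.z``.  Portions outside the raster are
    clipped.  ``diameter == 0`` yields the single pixel containing the center.
    """
    if diameter < 0:
        raise ValueError("diameter must be >= 0")
    row0, col0 = world_to_pixel(center, grid)  # raises if outside in-plane
    k = atlas_slice_index(center[2], grid)
    radius = diameter / 2.0
    s = grid.in_plane_spacing
    # candidate index window around the center
    reach = int(math.ceil(radius / s)) + 1
    rows = np.arange(max(0, row0 - reach), min(grid.n_y, row0 + reach + 1))
    cols = np.arange(max(0, col0 - reach), min(grid.n_x, col0 + reach + 1))
    cy = grid.origin[1] + (rows + 0.5) * s - center[1]
    cx = grid.origin[0] + (cols + 0.5) * s - center[0]
    d2 = cy[:, None] ** 2 + cx[None, :] ** 2
    rr, cc = np.nonzero(d2 <= radius * radius + 1e-12)
    pixels = frozenset(zip((rows[rr]).tolist(), (cols[cc]).tolist()))
    if not pixels:
        pixels = frozenset({(row0, col0)})
    return DiscMask(slice_index=k, pixels=pixels)
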