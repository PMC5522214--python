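"""Per-station density accumulation, morphological contouring and shading.

Every node disc is stamped onto its atlas slice; per-pixel overlap counts form
the station's density map — the metastasis-risk surrogate the atlas displays.
Station outlines come from the classical binary pipeline: union of discs,
morphological closing with a disc structuring element (bridging small gaps
between nearby nodes), then a Roberts-cross edge to trace the 1-px contour.
Density maps convert to grayscale by max-normalisation and to per-pixel alpha
for compositing; opacity grows with density (configurable inversion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import DiscMask, OutOfGridError, ReferenceGrid, rasterize_disc
from .transfer import LNcRecord

__all__ = [
    "DensityMap",
    "StationLayer",
    "AccumulationResult",
    "accumulate",
    "close_mask",
    "roberts_edge",
    "to_gray",
    "alpha_map",
    "high_risk_mask",
    "build_station_layer",
    "disc_footprint",
]

logger = logging.getLogger(__name__)


@dataclass
class DensityMap:
    """Stack of per-slice disc-overlap counts for one station.

    ``slices`` maps atlas slice index -> (n_y, n_x) non-negative int array;
    absent slices are implicitly zero.  ``max_count`` is the global maximum.
    """

    station: str
    shape: tuple[int, int]
    slices: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def max_count(self) -> int:
        if not self.slices:
            return 0
        return int(max(arr.max() for arr in self.slices.values()))

    @property
    def total_mass(self) -> int:
        """Sum of counts over all slices (= total disc pixel area stamped)."""
        return int(sum(arr.sum() for arr in self.slices.values()))

    def slice_array(self, index: int) -> np.ndarray:
        """Counts on one slice; zeros if the slice holds no density."""
        arr = self.slices.get(index)
        if arr is None:
            return np.zeros(self.shape, dtype=np.int64)
        return arr

    def add_disc(self, disc: DiscMask) -> None:
        arr = self.slices.get(disc.slice_index)
        if arr is None:
            arr = np.zeros(self.shape, dtype=np.int64)
            self.slices[disc.slice_index] = arr
        for r, c in disc.pixels:
            arr[r, c] += 1


@dataclass
class StationLayer:
    """Derived per-slice products of one station, keyed by slice index."""

    station: str
    union_mask: dict[int, np.ndarray]
    closed_mask: dict[int, np.ndarray]
    contour_mask: dict[int, np.ndarray]
    gray: dict[int, np.ndarray]
    alpha: dict[int, np.ndarray]


@dataclass
class AccumulationResult:
    """Density maps per station plus the records skipped as out-of-grid."""

    maps: dict[str, DensityMap]
    skipped: list[LNcRecord]

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


def accumulate(
    records: list[LNcRecord],
    grid: ReferenceGrid,
    diameter: float = 5.0,
) -> AccumulationResult:
    """Stamp every record's disc into its station's density map.

    Records whose center falls outside the grid extent are skipped with a
    warning and collected in the result's ``skipped`` list, so no record is
    ever lost silently.
    """
    maps: dict[str, DensityMap] = {}
    skipped: list[LNcRecord] = []
    for rec in records:
        try:
            disc = rasterize_disc(rec.position, diameter, grid)
        except OutOfGridError as exc:
            logger.warning(
                "skipping record (patient %s, station %s): %s",
                rec.patient_id, rec.station, exc,
            )
            skipped.append(rec)
            continue
        dmap = maps.get(rec.station)
        if dmap is None:
            dmap = DensityMap(station=rec.station, shape=grid.shape)
            maps[rec.station] = dmap
        dmap.add_disc(disc)
    return AccumulationResult(maps=maps, skipped=skipped)


def disc_footprint(radius_px: int) -> np.ndarray:
    """Discrete disc structuring element: offsets with ||(dr,dc)|| <= radius."""
    if radius_px < 0:
        raise ValueError("radius must be >= 0")
    r = np.arange(-radius_px, radius_px + 1)
    return (r[:, None] ** 2 + r[None, :] ** 2) <= radius_px**2


def close_mask(mask: np.ndarray, se_radius_px: int = 2) -> np.ndarray:
    """Morphological closing with a disc structuring element.

    The input is padded by the SE radius before dilation/erosion so the result
    equals the infinite-domain Minkowski closing restricted to the window —
    hence extensive (output ⊇ input) and idempotent, also near borders.
    """
    mask = np.asarray(mask, dtype=bool)
    if se_radius_px == 0:
        return mask.copy()
    se = disc_footprint(se_radius_px)
    r = se_radius_px
    padded = np.pad(mask, r, mode="constant", constant_values=False)
    closed = ndimage.binary_erosion(
        ndimage.binary_dilation(padded, structure=se), structure=se
    )
    return closed[r:-r, r:-r]


def roberts_edge(mask: np.ndarray) -> np.ndarray:
    """Roberts-cross edge of a binary mask.

    Pixel (r, c) is flagged iff ``|I(r,c) - I(r+1,c+1)| + |I(r+1,c) - I(r,c+1)|``
    is nonzero, with the last row/column replicated.  On binary input this
    flags exactly the pixels whose 2x2 forward window is mixed.
    """
    img = np.asarray(mask, dtype=np.int8)
    if img.ndim != 2:
        raise ValueError("expected a 2-D mask")
    ext = np.pad(img, ((0, 1), (0, 1)), mode="edge")
    g = np.abs(ext[:-1, :-1] - ext[1:, 1:]) + np.abs(ext[1:, :-1] - ext[:-1, 1:])
    return g > 0


def to_gray(d: DensityMap) -> dict[int, np.ndarray]:
    """Max-normalised grayscale per slice: ``count / max_count`` in [0, 1].

    An all-zero map yields all-zero grays (no division by zero).
    """
    m = d.max_count
    if m == 0:
        return {k: np.zeros(d.shape, dtype=float) for k in d.slices}
    return {k: arr / m for k, arr in d.slices.items()}


def alpha_map(gray: np.ndarray, alpha_max: float = 0.8) -> np.ndarray:
    """Opacity map: ``alpha_max * gray`` — denser regions render more opaque."""
    gray = np.asarray(gray, dtype=float)
    if gray.min() < 0 or gray.max() > 1:
        raise ValueError("gray values must lie in [0, 1]")
    if not 0 < alpha_max <= 1:
        raise ValueError("alpha_max must lie in (0, 1]")
    return alpha_max * gray


def high_risk_mask(
    d: DensityMap, fraction: float = 0.75
) -> dict[int, np.ndarray]:
    """Pixels with count >= fraction * max_count — the high-risk metastasis core."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    m = d.max_count
    if m == 0:
        raise ValueError("high-risk mask undefined for an all-zero density map")
    thr = fraction * m
    return {k: arr >= thr for k, arr in d.slices.items()}


def build_station_layer(
    d: DensityMap,
    se_radius_px: int = 2,
    alpha_max: float = 0.8,
    invert_alpha: bool = False,
) -> StationLayer:
    """Full per-station derivation: union -> closing -> contour -> gray/alpha.

    With ``invert_alpha`` the densest regions render most transparent
    (alpha = alpha_max * (1 - gray) on the support); default is opacity
    increasing with density.  Alpha is zero off the density support either way.
    """
    union = {k: arr > 0 for k, arr in d.slices.items()}
    closed = {k: close_mask(m, se_radius_px) for k, m in union.items()}
    contour = {k: roberts_edge(m) for k, m in closed.items()}
    gray = to_gray(d)
    alpha: dict[int, np.ndarray] = {}
    for k, g in gray.items():
        a = alpha_map(g, alpha_max)
        if invert_alpha:
            a = np.where(g > 0, alpha_max * (1.0 - g), 0.0)
        alpha[k] = a
    return StationLayer(
        station=d.station,
        union_mask=union,
        closed_mask=closed,
        contour_mask=contour,
        gray=gray,
        alpha=alpha,
    )
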