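"""Atlas rendering: station colors, CT windowing, alpha compositing, CTV margins.

The atlas shows each axial reference-CT slice windowed to soft tissue, with
every station's density overlaid in its assigned color; pixel opacity tracks
the local density.  Stations composite in ascending station order (1..15,
then 16a1..16b2), using the usual ``out = a*color + (1-a)*under`` rule.

The module also carries the per-station elective-CTV margin recommendations
(millimetre expansions around each station's guiding vessels) and the tube
expansion that turns a vessel centerline plus margin into a 3-D binary mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density import DensityMap, StationLayer
from .geometry import ReferenceGrid
from .stations import STATION_LABELS
from .transfer import VesselPolyline

__all__ = [
    "ColorScheme",
    "MarginTable",
    "WindowSetting",
    "default_color_scheme",
    "default_margin_table",
    "window_ct",
    "composite_slice",
    "select_atlas_slices",
    "expand_vessel_ctv",
]

# RGB values assigned by this package to the atlas color names; the scheme
# fixes names only, so these triples are documented constants of the artifact.
_COLOR_TABLE: tuple[tuple[str, str, tuple[int, int, int]], ...] = (
    ("1", "Rose red", (255, 0, 127)),
    ("2", "Prussian blue", (0, 49, 83)),
    ("3", "Green", (0, 128, 0)),
    ("4", "Yellow", (255, 255, 0)),
    ("5", "Dark green", (0, 100, 0)),
    ("6", "Acid blue", (0, 114, 188)),
    ("7", "Red", (255, 0, 0)),
    ("8", "Claybank", (166, 123, 81)),
    ("9", "Crimson", (220, 20, 60)),
    ("10", "Cyan", (0, 255, 255)),
    ("11", "Brown", (139, 69, 19)),
    ("12", "Dark blue", (0, 0, 139)),
    ("13", "Lemon yellow", (255, 247, 0)),
    ("14", "Orange", (255, 165, 0)),
    ("15", "Light blue", (173, 216, 230)),
    ("16a1", "Sky blue", (135, 206, 235)),
    ("16a2", "Purple", (128, 0, 128)),
    ("16b1", "Pale green", (152, 251, 152)),
    ("16b2", "Pink", (255, 192, 203)),
)


@dataclass(frozen=True)
class ColorScheme:
    """Station -> (color name, RGB) mapping; exactly one entry per station."""

    names: dict[str, str]
    rgb: dict[str, tuple[int, int, int]]

    def __post_init__(self) -> None:
        if set(self.rgb) != set(STATION_LABELS):
            raise ValueError("color scheme must cover exactly the 19 stations")
        triples = list(self.rgb.values())
        if len(set(triples)) != len(triples):
            raise ValueError("station colors must be pairwise distinct")


@dataclass(frozen=True)
class MarginTable:
    """Station -> (margin_lo, margin_hi) elective-CTV expansion in mm.

    ``provisional`` flags stations whose margin is a generic assignment rather
    than a station-specific recommendation.
    """

    margins: dict[str, tuple[float, float]]
    provisional: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if set(self.margins) != set(STATION_LABELS):
            raise ValueError("margin table must cover exactly the 19 stations")
        for st, (lo, hi) in self.margins.items():
            if not 0 < lo <= hi:
                raise ValueError(f"station {st}: need 0 < lo <= hi, got ({lo}, {hi})")


@dataclass(frozen=True)
class WindowSetting:
    """CT display window: center/width in Hounsfield units."""

    window_center: float = 40.0
    window_width: float = 400.0

    def __post_init__(self) -> None:
        if self.window_width <= 0:
            raise ValueError("window_width must be > 0")


def default_color_scheme() -> ColorScheme:
    """The atlas color scheme: 19 named colors, one per station."""
    return ColorScheme(
        names={st: name for st, name, _ in _COLOR_TABLE},
        rgb={st: rgb for st, _, rgb in _COLOR_TABLE},
    )


def default_margin_table() -> MarginTable:
    """Recommended elective-CTV margins around each station's guiding vessels.

    The lesser-curvature station (3) carries the highest metastatic rate and
    the widest margin (10-20 mm); the left-gastric trunk station (7) 5-15 mm;
    the heavily involved para-aortic substations 16a2/16b1 a flat 20 mm around
    the aorta and 16a1/16b2 10 mm; the remaining perigastric/regional stations
    5-10 mm.  Station 13 has no published recommendation and receives the
    generic 5-10 mm, flagged provisional.
    """
    margins: dict[str, tuple[float, float]] = {
        st: (5.0, 10.0)
        for st in ("1", "2", "4", "5", "6", "8", "9", "10", "11", "12", "14", "15")
    }
    margins["3"] = (10.0, 20.0)
    margins["7"] = (5.0, 15.0)
    margins["13"] = (5.0, 10.0)
    margins["16a2"] = (20.0, 20.0)
    margins["16b1"] = (20.0, 20.0)
    margins["16a1"] = (10.0, 10.0)
    margins["16b2"] = (10.0, 10.0)
    return MarginTable(margins=margins, provisional=frozenset({"13"}))


def window_ct(ct_slice: np.ndarray, window: WindowSetting) -> np.ndarray:
    """Map HU to 8-bit display gray via the center/width window (float array)."""
    lo = window.window_center - window.window_width / 2.0
    g = (np.asarray(ct_slice, dtype=float) - lo) / window.window_width
    return np.clip(g, 0.0, 1.0) * 255.0


def composite_slice(
    ct_slice: np.ndarray,
    layers: list[tuple[str, StationLayer]],
    slice_index: int,
    scheme: ColorScheme | None = None,
    window: WindowSetting | None = None,
) -> np.ndarray:
    """Render one atlas slice: windowed CT plus station overlays, uint8 RGB.

    ``layers`` pairs station labels with their StationLayer; stations are drawn
    in ascending station order regardless of input order.  Per pixel/channel:
    ``out = alpha * color + (1 - alpha) * under``.  All-zero alphas leave the
    background untouched.
    """
    scheme = scheme or default_color_scheme()
    window = window or WindowSetting()
    bg = window_ct(ct_slice, window)
    img = np.repeat(bg[:, :, None], 3, axis=2)
    order = {st: i for i, st in enumerate(STATION_LABELS)}
    for station, layer in sorted(layers, key=lambda sl: order[sl[0]]):
        a = layer.alpha.get(slice_index)
        if a is None:
            continue
        if a.shape != bg.shape:
            raise ValueError(
                f"layer shape {a.shape} does not match CT slice shape {bg.shape}"
            )
        color = np.asarray(scheme.rgb[station], dtype=float)
        img = a[:, :, None] * color[None, None, :] + (1.0 - a[:, :, None]) * img
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def select_atlas_slices(
    maps: dict[str, DensityMap], grid: ReferenceGrid
) -> list[int]:
    """Atlas slices carrying any station density, cranial to caudal."""
    hot: set[int] = set()
    for dmap in maps.values():
        for k, arr in dmap.slices.items():
            if arr.any():
                hot.add(k)
    return sorted(i for i in hot if 0 <= i < grid.n_slices)


def expand_vessel_ctv(
    vessel: VesselPolyline, margin: float, grid: ReferenceGrid
) -> np.ndarray:
    """3-D isotropic tube of radius *margin* (mm) around a vessel centerline.

    Returns a boolean (n_slices, n_y, n_x) mask of voxels whose center lies
    within the margin of any polyline segment.  Voxel centers follow the grid
    conventions: in-plane ``origin + (idx + 0.5) * spacing``, craniocaudal
    slice centers at ``z_min + (k + 0.5) * thickness``.  The voxel containing
    each polyline vertex is always included (so sub-voxel margins still mark
    the centerline), and vertices outside the grid are ignored.
    """
    if margin <= 0:
        raise ValueError("margin must be > 0")
    s = grid.in_plane_spacing
    t = grid.atlas_slice_thickness
    xs = grid.origin[0] + (np.arange(grid.n_x) + 0.5) * s
    ys = grid.origin[1] + (np.arange(grid.n_y) + 0.5) * s
    zs = grid.z_min + (np.arange(grid.n_slices) + 0.5) * t
    mask = np.zeros((grid.n_slices, grid.n_y, grid.n_x), dtype=bool)
    pts = vessel.as_array()
    for v in pts:
        if grid.contains((float(v[0]), float(v[1]), float(v[2]))):
            col = int(np.floor((v[0] - grid.origin[0]) / s))
            row = int(np.floor((v[1] - grid.origin[1]) / s))
            k = int(np.floor((v[2] - grid.z_min) / t))
            mask[k, row, col] = True
    for a, b in zip(pts[:-1], pts[1:]):
        # bounding sub-box of the segment, expanded by the margin
        lo = np.minimum(a, b) - margin - max(s, t)
        hi = np.maximum(a, b) + margin + max(s, t)
        ix = np.nonzero((xs >= lo[0]) & (xs <= hi[0]))[0]
        iy = np.nonzero((ys >= lo[1]) & (ys <= hi[1]))[0]
        iz = np.nonzero((zs >= lo[2]) & (zs <= hi[2]))[0]
        if not (ix.size and iy.size and iz.size):
            continue
        Z, Y, X = np.meshgrid(zs[iz], ys[iy], xs[ix], indexing="ij")
        p = np.stack([X, Y, Z], axis=-1)
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            proj = a
        else:
            tt = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
            proj = a + tt[..., None] * ab
        d = np.linalg.norm(p - proj, axis=-1)
        sub = d <= margin + 1e-12
        mask[np.ix_(iz, iy, ix)] |= sub
    return mask
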