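"""Synthetic reference phantom and station-wise node samples.

No clinical images ship with this package, so every pipeline stage is
exercised on a synthetic standard patient: a soft-tissue CT volume with an
ellipsoidal half-filled "stomach", bright tubular vessels traced along 16
named centerlines, and a gastric-wall polyline.  Node centers are drawn
around short anchor segments of the anatomically corresponding vessel for
each of the 19 stations.

The sampling statistics mirror the clinical cohort the atlas summarises:
per-station node counts uniform in [31, 599], an overall PRLN proportion of
62.2%, and an isotropic 3-D Gaussian scatter (default sigma 6 mm) around the
anchor curve.  Everything is deterministic given the seed, and the generating
truth (anchor centroids, true PRLN probability) is returned so recovery tests
can close the loop.

The phantom's vessel layout is schematic: branch topology and rough abdominal
placement are respected (celiac trunk giving rise to LGA/SA/CHA, the
para-aortic vessel roots on a common vertical midline standing in for the
aorta), but no attempt is made at realistic CT texture or patient
variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ReferenceGrid
from .stations import GASTRIC_WALL, STATION_LABELS, VESSEL_NAMES
from .transfer import LNcRecord, VesselPolyline

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_phantom",
    "sample_lncs",
    "STATION_ANCHORS",
]

# Schematic vessel centerlines of the phantom, mm in the reference frame.
# x grows to the patient's left, y posteriorly, z caudally.  The roots of
# PISA, CA, SMA and IMA sit on the midline column (x=110, y=120) that stands
# in for the aorta.
_VESSEL_POINTS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "PISA": ((110.0, 120.0, 40.0), (98.0, 102.0, 36.0), (88.0, 88.0, 33.0)),
    "CA": ((110.0, 120.0, 80.0), (110.0, 104.0, 80.0), (110.0, 92.0, 79.0)),
    "LGA": (
        (110.0, 92.0, 78.0),
        (101.0, 78.0, 70.0),
        (93.0, 67.0, 60.0),
        (88.0, 60.0, 50.0),
    ),
    "RGA": ((70.0, 80.0, 70.0), (80.0, 71.0, 72.0), (90.0, 65.0, 74.0)),
    "GBA": ((170.0, 70.0, 60.0), (175.0, 64.0, 52.0), (178.0, 60.0, 45.0)),
    "LGEA": ((170.0, 80.0, 70.0), (161.0, 68.0, 79.0), (152.0, 57.0, 88.0)),
    "RGEA": (
        (80.0, 70.0, 110.0),
        (97.0, 61.0, 112.0),
        (120.0, 56.0, 112.0),
        (142.0, 56.0, 108.0),
    ),
    "RGEV": ((82.0, 74.0, 112.0), (99.0, 65.0, 114.0), (118.0, 60.0, 114.0)),
    "PHA": ((75.0, 85.0, 80.0), (70.0, 79.0, 71.0), (68.0, 75.0, 62.0)),
    "CHA": ((110.0, 92.0, 80.0), (93.0, 89.0, 80.0), (75.0, 85.0, 80.0)),
    "SA": (
        (110.0, 92.0, 80.0),
        (127.0, 87.0, 78.0),
        (150.0, 85.0, 76.0),
        (172.0, 88.0, 74.0),
    ),
    "MCA": ((112.0, 105.0, 130.0), (128.0, 100.0, 139.0), (145.0, 98.0, 148.0)),
    "GDA": ((75.0, 85.0, 80.0), (72.0, 89.0, 92.0), (70.0, 92.0, 102.0)),
    "SMA": (
        (110.0, 120.0, 100.0),
        (110.0, 110.0, 115.0),
        (112.0, 105.0, 130.0),
        (114.0, 105.0, 145.0),
    ),
    "SMV": ((120.0, 110.0, 105.0), (122.0, 105.0, 120.0), (124.0, 103.0, 135.0)),
    "IMA": ((110.0, 120.0, 140.0), (108.0, 115.0, 150.0), (106.0, 112.0, 160.0)),
}

# Stomach ellipsoid of the phantom: center and semi-axes, mm.
_STOMACH_CENTER = np.array([135.0, 75.0, 85.0])
_STOMACH_AXES = np.array([45.0, 30.0, 40.0])

#: Station -> (anchor vessel, vertex slice) defining the short anchor segment
#: node centers scatter around.  The mapping follows the stations' guiding
#: vessels: perigastric stations on the gastric arteries/arcades, regional
#: stations on the celiac branches, para-aortic substations on the midline
#: vessel roots that trace the aortic axis.
STATION_ANCHORS: dict[str, tuple[str, tuple[int, int]]] = {
    "1": ("LGA", (2, 4)),    # ascending branch, near the cardia
    "2": ("PISA", (1, 3)),   # esophageal branch of the left inferior phrenic
    "3": ("LGA", (1, 3)),    # lesser-curvature arcade
    "4": ("LGEA", (1, 3)),   # greater curvature, left gastroepiploic
    "5": ("RGA", (1, 3)),    # suprapyloric, right gastric
    "6": ("RGEA", (0, 2)),   # infrapyloric, proximal right gastroepiploic
    "7": ("LGA", (0, 2)),    # left gastric trunk
    "8": ("CHA", (1, 3)),    # common hepatic
    "9": ("CA", (0, 3)),     # celiac trunk
    "10": ("GBA", (1, 3)),   # splenic hilum
    "11": ("SA", (0, 2)),    # proximal splenic artery
    "12": ("PHA", (0, 2)),   # hepatoduodenal ligament
    "13": ("GDA", (1, 3)),   # posterior pancreatic head
    "14": ("SMV", (0, 2)),   # superior mesenteric vein
    "15": ("MCA", (1, 3)),   # middle colic vessels
    "16a1": ("PISA", (0, 2)),  # aortic hiatus (midline PISA root)
    "16a2": ("CA", (0, 2)),    # celiac origin (midline CA root)
    "16b1": ("SMA", (0, 2)),   # below renal vein (midline SMA root)
    "16b2": ("IMA", (0, 2)),   # IMA origin (midline IMA root)
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults reproduce the cohort-level conditions."""

    seed: int = 0
    n_min: int = 31
    n_max: int = 599
    prln_probability: float = 0.622
    scatter_sigma: float = 6.0
    grid: ReferenceGrid = field(default_factory=ReferenceGrid)
    background_hu: float = 40.0
    stomach_hu: float = 0.0
    vessel_hu: float = 200.0
    vessel_radius: float = 3.0
    noise_hu: float = 10.0

    def __post_init__(self) -> None:
        if not 0 <= self.prln_probability <= 1:
            raise ValueError("prln_probability must lie in [0, 1]")
        if not 0 < self.n_min <= self.n_max:
            raise ValueError("need 0 < n_min <= n_max")
        if self.scatter_sigma <= 0:
            raise ValueError("scatter_sigma must be > 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating truth returned alongside sampled records."""

    prln_probability: float
    anchor_centroids: dict[str, tuple[float, float, float]]
    station_counts: dict[str, int]


def _gastric_wall_polyline(n: int = 48) -> VesselPolyline:
    """Equatorial ring of the stomach ellipsoid as the gastric-wall landmark."""
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    pts = tuple(
        (
            float(_STOMACH_CENTER[0] + _STOMACH_AXES[0] * np.cos(t)),
            float(_STOMACH_CENTER[1] + _STOMACH_AXES[1] * np.sin(t)),
            float(_STOMACH_CENTER[2]),
        )
        for t in theta
    )
    return VesselPolyline(name=GASTRIC_WALL, points=pts)


def generate_phantom(
    cfg: SyntheticConfig,
) -> tuple[np.ndarray, dict[str, VesselPolyline]]:
    """Build the reference volume and the 17 landmark polylines.

    Returns ``(volume, polylines)`` where ``volume`` is a float32 HU array of
    shape (n_slices, n_y, n_x): soft-tissue background with mild Gaussian
    noise, the stomach ellipsoid at water density, and bright vessel tubes.
    Deterministic given ``cfg.seed``.
    """
    grid = cfg.grid
    polylines = {
        name: VesselPolyline(name=name, points=_VESSEL_POINTS[name])
        for name in VESSEL_NAMES
    }
    for poly in polylines.values():
        for p in poly.points:
            if not grid.contains(p):
                raise ValueError(
                    f"grid too small: vessel {poly.name} vertex {p} outside extent"
                )
    polylines[GASTRIC_WALL] = _gastric_wall_polyline()

    rng = np.random.default_rng(cfg.seed)
    shape = (grid.n_slices, grid.n_y, grid.n_x)
    vol = cfg.background_hu + cfg.noise_hu * rng.standard_normal(shape)

    s = grid.in_plane_spacing
    xs = grid.origin[0] + (np.arange(grid.n_x) + 0.5) * s
    ys = grid.origin[1] + (np.arange(grid.n_y) + 0.5) * s
    zs = grid.z_min + (np.arange(grid.n_slices) + 0.5) * grid.atlas_slice_thickness
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")

    ell = (
        ((X - _STOMACH_CENTER[0]) / _STOMACH_AXES[0]) ** 2
        + ((Y - _STOMACH_CENTER[1]) / _STOMACH_AXES[1]) ** 2
        + ((Z - _STOMACH_CENTER[2]) / _STOMACH_AXES[2]) ** 2
    )
    vol[ell <= 1.0] = cfg.stomach_hu

    # bright tubes along each vessel centerline
    from .render import expand_vessel_ctv  # local import avoids a cycle

    for name in VESSEL_NAMES:
        tube = expand_vessel_ctv(polylines[name], cfg.vessel_radius, grid)
        vol[tube] = cfg.vessel_hu
    return vol.astype(np.float32), polylines


def _anchor_points(
    station: str, vessels: dict[str, VesselPolyline]
) -> np.ndarray:
    name, (i0, i1) = STATION_ANCHORS[station]
    pts = vessels[name].as_array()[i0:i1]
    if len(pts) < 2:
        raise ValueError(f"anchor segment for station {station} has < 2 points")
    return pts


def _curve_centroid(pts: np.ndarray) -> np.ndarray:
    """Arc-length-weighted centroid of a polyline (uniform-on-curve mean)."""
    a, b = pts[:-1], pts[1:]
    lengths = np.linalg.norm(b - a, axis=1)
    mids = (a + b) / 2.0
    return (lengths[:, None] * mids).sum(axis=0) / lengths.sum()


def _sample_on_curve(pts: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """n points uniform by arc length along a polyline."""
    a, b = pts[:-1], pts[1:]
    lengths = np.linalg.norm(b - a, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    u = rng.uniform(0.0, cum[-1], size=n)
    seg = np.clip(np.searchsorted(cum, u, side="right") - 1, 0, len(lengths) - 1)
    frac = (u - cum[seg]) / lengths[seg]
    return a[seg] + frac[:, None] * (b[seg] - a[seg])


def sample_lncs(
    cfg: SyntheticConfig, vessels: dict[str, VesselPolyline]
) -> tuple[list[LNcRecord], SyntheticTruth]:
    """Draw station-wise node records around their anchor segments.

    Per station: ``n ~ U{n_min..n_max}`` nodes at (uniform anchor-curve point
    + isotropic Gaussian, sd ``scatter_sigma``), each PRLN with probability
    ``prln_probability``.  Returns the records (synthetic patient ids encode
    the station) and the generating truth for recovery checks.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[LNcRecord] = []
    centroids: dict[str, tuple[float, float, float]] = {}
    counts: dict[str, int] = {}
    for station in STATION_LABELS:
        pts = _anchor_points(station, vessels)
        n = int(rng.integers(cfg.n_min, cfg.n_max + 1))
        counts[station] = n
        base = _sample_on_curve(pts, n, rng)
        pos = base + cfg.scatter_sigma * rng.standard_normal((n, 3))
        prln = rng.random(n) < cfg.prln_probability
        for i in range(n):
            records.append(
                LNcRecord(
                    patient_id=f"synth-{station}-{i:04d}",
                    station=station,
                    evidence="PRLN" if prln[i] else "RLN",
                    position=(
                        float(pos[i, 0]),
                        float(pos[i, 1]),
                        float(pos[i, 2]),
                    ),
                )
            )
        c = _curve_centroid(pts)
        centroids[station] = (float(c[0]), float(c[1]), float(c[2]))
    truth = SyntheticTruth(
        prln_probability=cfg.prln_probability,
        anchor_centroids=centroids,
        station_counts=counts,
    )
    return records, truth
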