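"""PRLN/RLN breakdown tables and craniocaudal density histograms.

Each node carries an evidence class: PRLN (pathological- and radiological-
positive) or RLN (radiological-positive only).  The breakdown reports counts
and percentages per station and overall; percentages are rounded
half-away-from-zero to one decimal, matching the atlas's printed style.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .density import DensityMap
from .geometry import ReferenceGrid
from .stations import STATION_LABELS
from .transfer import LNcRecord

__all__ = [
    "StationStats",
    "breakdown",
    "per_slice_histogram",
    "stats_table",
    "density_weighted_centroid",
]


def _round1(x: float) -> float:
    """Round to one decimal, halves away from zero (printed-table style)."""
    sign = -1.0 if x < 0 else 1.0
    return sign * math.floor(abs(x) * 10 + 0.5) / 10


@dataclass(frozen=True)
class StationStats:
    """Evidence-class counts and percentages for one station (or 'ALL')."""

    station: str
    n_prln: int
    n_rln: int

    @property
    def n_total(self) -> int:
        return self.n_prln + self.n_rln

    @property
    def pct_prln(self) -> float | None:
        """Percent PRLN, one decimal; None when the station holds no nodes."""
        if self.n_total == 0:
            return None
        return _round1(100.0 * self.n_prln / self.n_total)

    @property
    def pct_rln(self) -> float | None:
        if self.n_total == 0:
            return None
        return _round1(100.0 * self.n_rln / self.n_total)


def breakdown(
    records: list[LNcRecord],
) -> tuple[StationStats, list[StationStats]]:
    """Overall and per-station PRLN/RLN counts.

    Returns ``(overall, per_station)`` where ``per_station`` lists all 19
    stations in atlas order, including stations with zero nodes.  Record
    construction already enforces the station/evidence vocabularies.
    """
    prln = {st: 0 for st in STATION_LABELS}
    rln = {st: 0 for st in STATION_LABELS}
    for rec in records:
        if rec.evidence == "PRLN":
            prln[rec.station] += 1
        else:
            rln[rec.station] += 1
    per_station = [
        StationStats(station=st, n_prln=prln[st], n_rln=rln[st])
        for st in STATION_LABELS
    ]
    overall = StationStats(
        station="ALL", n_prln=sum(prln.values()), n_rln=sum(rln.values())
    )
    return overall, per_station


def per_slice_histogram(d: DensityMap) -> list[tuple[int, int]]:
    """Per-slice total counts, cranial to caudal (only slices with storage)."""
    return [(k, int(d.slices[k].sum())) for k in sorted(d.slices)]


def density_weighted_centroid(
    d: DensityMap, grid: ReferenceGrid
) -> tuple[float, float, float]:
    """Count-weighted world centroid of a station's density map, mm.

    In-plane coordinates are pixel centers; the craniocaudal coordinate is the
    atlas-slice center.  Summarises where a station's metastatic burden sits;
    used for placement QA and synthetic-recovery checks.
    """
    if d.max_count == 0:
        raise ValueError("centroid undefined for an all-zero density map")
    s = grid.in_plane_spacing
    total = 0.0
    acc = np.zeros(3)
    for k, arr in d.slices.items():
        rows, cols = np.nonzero(arr)
        if rows.size == 0:
            continue
        w = arr[rows, cols].astype(float)
        xs = grid.origin[0] + (cols + 0.5) * s
        ys = grid.origin[1] + (rows + 0.5) * s
        acc[0] += float((w * xs).sum())
        acc[1] += float((w * ys).sum())
        acc[2] += float(w.sum()) * grid.slice_center_z(k)
        total += float(w.sum())
    acc /= total
    return (float(acc[0]), float(acc[1]), float(acc[2]))


def stats_table(records: list[LNcRecord]) -> pd.DataFrame:
    """Breakdown as a tidy table: one row per station plus the 'ALL' row."""
    overall, per_station = breakdown(records)
    rows = [
        {
            "station": s.station,
            "n_prln": s.n_prln,
            "n_rln": s.n_rln,
            "n_total": s.n_total,
            "pct_prln": s.pct_prln,
            "pct_rln": s.pct_rln,
        }
        for s in per_station + [overall]
    ]
    return pd.DataFrame(rows)
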