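"""Vessel-guided placement of lymph-node centers on the reference frame.

Each metastatic node is observed in a patient's CT and must be re-drawn at the
*equivalent location* on the single reference patient, preserving its relative
distances to named landmarks (the 16 reference vessels and the gastric wall).
The clinical procedure is manual; this module codifies it as inverse-distance-
weighted (IDW) offset transfer over the supplied landmark correspondences:

    d_i = ||q - p_i||,   w_i ∝ d_i^(-power)
    place(q) = Σ_i w_i * (r_i + (q - p_i)) / Σ_i w_i

where ``p_i``/``r_i`` are a landmark's patient/reference positions and ``q``
the node center in the patient frame.  Each landmark proposes "keep your
offset from me"; nearby landmarks dominate.  A node exactly on a landmark
snaps to that landmark's reference position.

Confluent nodes (indistinguishable on imaging) are merged to the geometric
center of their cluster; distinguishable nodes are kept individually.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .geometry import WorldPoint
from .stations import (
    LANDMARK_NAMES,
    validate_evidence,
    validate_station,
)

__all__ = [
    "VesselPolyline",
    "LandmarkCorrespondence",
    "LNcRecord",
    "place_lnc",
    "merge_confluent",
    "nearest_vessel_distance",
]


@dataclass(frozen=True)
class VesselPolyline:
    """Named ordered 3-D centerline of a reference vessel (or the gastric wall)."""

    name: str
    points: tuple[WorldPoint, ...]

    def __post_init__(self) -> None:
        if self.name not in LANDMARK_NAMES:
            raise ValueError(
                f"unknown landmark name {self.name!r}; expected one of {LANDMARK_NAMES}"
            )
        if len(self.points) < 2:
            raise ValueError("a polyline needs at least 2 points")
        for a, b in zip(self.points, self.points[1:]):
            if a == b:
                raise ValueError("consecutive polyline points must be distinct")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float)


@dataclass(frozen=True)
class LandmarkCorrespondence:
    """One landmark seen in both frames: patient position and reference position."""

    label: str
    patient_point: WorldPoint
    reference_point: WorldPoint


@dataclass(frozen=True)
class LNcRecord:
    """One metastatic-node center on the reference frame.

    ``station`` is one of the 19 labels; ``evidence`` distinguishes nodes with
    pathological confirmation (PRLN) from radiology-only calls (RLN).
    """

    patient_id: str
    station: str
    evidence: str
    position: WorldPoint

    def __post_init__(self) -> None:
        validate_station(self.station)
        validate_evidence(self.evidence)


def place_lnc(
    patient_point: WorldPoint,
    correspondences: list[LandmarkCorrespondence],
    power: float = 2.0,
) -> WorldPoint:
    """Transfer a node center to the reference frame by IDW offset transfer.

    With a single correspondence this is pure offset transfer
    ``r_1 + (q - p_1)``; a node coincident with landmark *i* returns ``r_i``
    exactly.  The map interpolates the landmarks and is equivariant under a
    common rigid translation of both frames.
    """
    if not correspondences:
        raise ValueError("at least one landmark correspondence is required")
    if power <= 0:
        raise ValueError("power must be positive")
    q = np.asarray(patient_point, dtype=float)
    p = np.asarray([c.patient_point for c in correspondences], dtype=float)
    r = np.asarray([c.reference_point for c in correspondences], dtype=float)
    d = np.linalg.norm(q - p, axis=1)
    hit = np.nonzero(d == 0.0)[0]
    if hit.size:
        return tuple(float(v) for v in r[hit[0]])
    w = d ** (-power)
    w /= w.sum()
    candidates = r + (q - p)
    out = (w[:, None] * candidates).sum(axis=0)
    return (float(out[0]), float(out[1]), float(out[2]))


def merge_confluent(
    points: list[WorldPoint], merge_radius: float = 5.0
) -> list[WorldPoint]:
    """Replace single-linkage clusters of nearby points by their centroid.

    Points whose pairwise chain links are all <= *merge_radius* (mm) form one
    confluent mass and are represented by its geometric central position;
    points farther apart are preserved individually.  Output order follows
    first appearance of each cluster in the input.
    """
    if merge_radius < 0:
        raise ValueError("merge_radius must be >= 0")
    if not points:
        return []
    arr = np.asarray(points, dtype=float)
    if len(points) == 1:
        return [tuple(map(float, arr[0]))]
    labels = fcluster(
        linkage(arr, method="single"), t=merge_radius, criterion="distance"
    )
    out: list[WorldPoint] = []
    seen: dict[int, None] = {}
    for lab in labels:
        if lab not in seen:
            seen[lab] = None
            centroid = arr[labels == lab].mean(axis=0)
            out.append(tuple(float(v) for v in centroid))
    return out


def nearest_vessel_distance(p: WorldPoint, vessel: VesselPolyline) -> float:
    """Minimum distance (mm) from a point to a vessel centerline polyline."""
    q = np.asarray(p, dtype=float)
    pts = vessel.as_array()
    a, b = pts[:-1], pts[1:]
    ab = b - a
    denom = (ab * ab).sum(axis=1)
    t = np.clip(((q - a) * ab).sum(axis=1) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.linalg.norm(q - proj, axis=1).min())
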