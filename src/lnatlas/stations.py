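"""Fixed vocabularies of the gastric lymph-node atlas.

The JGCA scheme divides the stomach's lymphatic drainage into 16 numbered
stations; station 16 (para-aortic) splits into 16a1/16a2/16b1/16b2, giving the
19 labels used throughout this package.  Station ``14`` denotes 14v, the
superior mesenteric vein nodes.  Sixteen named reference vessels plus the
gastric wall serve as the landmarks for vessel-guided node placement.
"""

from __future__ import annotations

#: The 19 station labels, in atlas draw order (1..15, then the 16 substations).
STATION_LABELS: tuple[str, ...] = (
    "1", "2", "3", "4", "5", "6", "7", "8", "9", "10",
    "11", "12", "13", "14", "15", "16a1", "16a2", "16b1", "16b2",
)

#: Evidence classes per node: pathological-and-radiological positive vs
#: radiological-only positive.
EVIDENCE_CLASSES: tuple[str, str] = ("PRLN", "RLN")

#: The 16 reference vessels (abbreviations as printed on the atlas figure).
VESSEL_NAMES: tuple[str, ...] = (
    "PISA",  # phrenica inferior sinistra artery
    "LGA",   # left gastric artery
    "RGA",   # right gastric artery
    "GBA",   # gastricae breves artery
    "LGEA",  # left gastroepiploic artery
    "RGEA",  # right gastroepiploic artery
    "RGEV",  # right gastroepiploic vein
    "PHA",   # proper hepatic artery
    "CHA",   # common hepatic artery
    "CA",    # celiac artery
    "SA",    # splenic artery
    "MCA",   # middle colic artery
    "GDA",   # gastroduodenal artery
    "SMA",   # superior mesenteric artery
    "SMV",   # superior mesenteric vein
    "IMA",   # inferior mesenteric artery
)

GASTRIC_WALL = "GASTRIC_WALL"

#: Every legal landmark label: the 16 vessels plus the gastric wall.
LANDMARK_NAMES: tuple[str, ...] = VESSEL_NAMES + (GASTRIC_WALL,)

#: Human-readable anatomical names per station (for legends and reports).
STATION_NAMES: dict[str, str] = {
    "1": "Right pericardial LNs",
    "2": "Left pericardial LNs",
    "3": "Lesser curvature LNs",
    "4": "Left greater curvature LNs",
    "5": "Suprapyloric LNs",
    "6": "Infrapyloric LNs",
    "7": "Left gastric artery trunk LNs",
    "8": "Common hepatic artery LNs",
    "9": "Celiac artery LNs",
    "10": "Splenic hilar LNs",
    "11": "Splenic artery LNs",
    "12": "Hepatoduodenal ligament LNs",
    "13": "Posterior pancreatic head LNs",
    "14": "Superior mesenteric vein LNs (14v)",
    "15": "Middle colic vessels LNs",
    "16a1": "Para-aortic LNs, aortic hiatus",
    "16a2": "Para-aortic LNs, celiac origin to left renal vein",
    "16b1": "Para-aortic LNs, left renal vein to IMA origin",
    "16b2": "Para-aortic LNs, IMA origin to aortic bifurcation",
}


def validate_station(label: str) -> str:
    """Return *label* if it is one of the 19 station labels, else raise."""
    if label not in STATION_LABELS:
        raise ValueError(
            f"unknown station label {label!r}; expected one of {STATION_LABELS}"
        )
    return label


def validate_evidence(token: str) -> str:
    """Return *token* if it is PRLN or RLN, else raise."""
    if token not in EVIDENCE_CLASSES:
        raise ValueError(
            f"unknown evidence class {token!r}; expected PRLN or RLN"
        )
    return token
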