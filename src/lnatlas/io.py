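"""Readers, writers and the end-to-end pipeline orchestration.

File formats: the node table is one consolidated CSV (header
``patient_id,station,evidence,x_mm,y_mm,z_mm``); vessels travel as JSON
(name + point list, mm); volumes and per-station density stacks as NIfTI;
the breakdown as ``stats.csv``; atlas slices as PNG.  A converter stub for
per-structure coordinate exports (one file per contoured node, as produced
by planning workstations) is provided as an extension point.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .density import accumulate, build_station_layer
from .geometry import ReferenceGrid
from .render import (
    WindowSetting,
    composite_slice,
    default_color_scheme,
    select_atlas_slices,
)
from .stations import STATION_NAMES
from .stats import per_slice_histogram, stats_table
from .transfer import LNcRecord, VesselPolyline

__all__ = [
    "PipelineConfig",
    "read_lnc_table",
    "write_lnc_table",
    "read_vessels",
    "write_vessels",
    "read_volume",
    "write_volume",
    "load_config",
    "run_build",
    "convert_structure_files",
]

logger = logging.getLogger(__name__)

_LNC_COLUMNS = ["patient_id", "station", "evidence", "x_mm", "y_mm", "z_mm"]


@dataclass
class PipelineConfig:
    """Everything the atlas build needs; mirrors the YAML config schema."""

    reference_volume: str | None = None
    vessels: str | None = None
    lnc_table: str | None = None
    output_dir: str = "out"
    grid: ReferenceGrid = field(default_factory=ReferenceGrid)
    disc_diameter_mm: float = 5.0
    se_radius_px: int = 2
    alpha_max: float = 0.8
    invert_alpha: bool = False
    window: WindowSetting = field(default_factory=WindowSetting)
    high_risk_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.disc_diameter_mm <= 0:
            raise ValueError("disc_diameter_mm must be > 0")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML pipeline config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    grid = ReferenceGrid(**raw.pop("grid", {}))
    window = WindowSetting(**raw.pop("window", {}))
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(grid=grid, window=window, **raw)


def read_lnc_table(path: str | Path) -> list[LNcRecord]:
    """Read the consolidated node-center CSV into validated records.

    Malformed rows raise with their (1-based data) row number; an empty file
    yields an empty list with a warning.
    """
    df = pd.read_csv(path, dtype={"station": str, "patient_id": str})
    missing = [c for c in _LNC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        logger.warning("%s: empty node table", path)
        return []
    records: list[LNcRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                LNcRecord(
                    patient_id=str(row.patient_id),
                    station=str(row.station),
                    evidence=str(row.evidence),
                    position=(float(row.x_mm), float(row.y_mm), float(row.z_mm)),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, row {i}: {exc}") from exc
    return records


def write_lnc_table(records: list[LNcRecord], path: str | Path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "station": r.station,
            "evidence": r.evidence,
            "x_mm": r.position[0],
            "y_mm": r.position[1],
            "z_mm": r.position[2],
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_LNC_COLUMNS).to_csv(path, index=False)


def read_vessels(path: str | Path) -> dict[str, VesselPolyline]:
    """Read landmark polylines from JSON (list of {name, points})."""
    data = json.loads(Path(path).read_text())
    out: dict[str, VesselPolyline] = {}
    for entry in data:
        poly = VesselPolyline(
            name=entry["name"],
            points=tuple(tuple(float(v) for v in p) for p in entry["points"]),
        )
        out[poly.name] = poly
    return out


def write_vessels(vessels: dict[str, VesselPolyline], path: str | Path) -> None:
    data = [
        {"name": v.name, "points": [list(p) for p in v.points]}
        for v in vessels.values()
    ]
    Path(path).write_text(json.dumps(data, indent=1))


def _grid_affine(grid: ReferenceGrid) -> np.ndarray:
    """Voxel->world affine for (slice, row, col) volumes written to NIfTI."""
    aff = np.diag(
        [
            grid.in_plane_spacing,
            grid.in_plane_spacing,
            grid.atlas_slice_thickness,
            1.0,
        ]
    )
    aff[:3, 3] = [grid.origin[0], grid.origin[1], grid.z_min]
    return aff


def write_volume(vol: np.ndarray, grid: ReferenceGrid, path: str | Path) -> None:
    """Write a (n_slices, n_y, n_x) array as NIfTI in x/y/z voxel order."""
    img = nib.Nifti1Image(np.transpose(vol, (2, 1, 0)), _grid_affine(grid))
    nib.save(img, str(path))


def read_volume(path: str | Path, grid: ReferenceGrid) -> np.ndarray:
    """Read a NIfTI written by :func:`write_volume` back to (slice, row, col)."""
    img = nib.load(str(path))
    return np.transpose(np.asarray(img.dataobj), (2, 1, 0))


def run_build(cfg: PipelineConfig) -> dict:
    """Execute the full atlas build and write all artifacts.

    Stages: accumulate -> close -> edge -> gray/alpha -> composite -> stats.
    Returns the run report (also written to ``report.json``): record counts,
    skipped records, per-station slice histograms and output paths.
    Deterministic for fixed inputs and config.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = cfg.grid

    if cfg.lnc_table is None:
        raise ValueError("pipeline config needs an lnc_table path")
    records = read_lnc_table(cfg.lnc_table)
    logger.info("stage accumulate: %d records", len(records))
    acc = accumulate(records, grid, diameter=cfg.disc_diameter_mm)

    layers = {}
    for station, dmap in acc.maps.items():
        layers[station] = build_station_layer(
            dmap,
            se_radius_px=cfg.se_radius_px,
            alpha_max=cfg.alpha_max,
            invert_alpha=cfg.invert_alpha,
        )
        write_volume(
            np.stack(
                [dmap.slice_array(k).astype(np.float32) for k in range(grid.n_slices)]
            ),
            grid,
            out / f"density_{station}.nii.gz",
        )

    if cfg.reference_volume is not None:
        volume = read_volume(cfg.reference_volume, grid)
    else:
        volume = np.zeros((grid.n_slices, grid.n_y, grid.n_x), dtype=np.float32)

    scheme = default_color_scheme()
    selected = select_atlas_slices(acc.maps, grid)
    logger.info("stage composite: %d atlas slices", len(selected))
    for k in selected:
        rgb = composite_slice(
            volume[k], list(layers.items()), k, scheme=scheme, window=cfg.window
        )
        Image.fromarray(rgb).save(out / f"atlas_z{k:03d}.png")
    _write_legend(scheme, out / "legend.png")
    (out / "colors.json").write_text(
        json.dumps(
            {
                st: {"name": scheme.names[st], "rgb": list(scheme.rgb[st])}
                for st in scheme.rgb
            },
            indent=1,
        )
    )

    table = stats_table(records)
    table.to_csv(out / "stats.csv", index=False)

    report = {
        "n_records": len(records),
        "n_used": len(records) - acc.n_skipped,
        "skipped": [
            {"patient_id": r.patient_id, "station": r.station} for r in acc.skipped
        ],
        "atlas_slices": selected,
        "per_station_slices": {
            st: per_slice_histogram(dmap) for st, dmap in sorted(acc.maps.items())
        },
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report


def _write_legend(scheme, path: Path) -> None:
    """Simple swatch legend, one row per station."""
    row_h, sw, width = 22, 36, 360
    img = Image.new("RGB", (width, row_h * len(scheme.rgb)), (255, 255, 255))
    from PIL import ImageDraw

    draw = ImageDraw.Draw(img)
    for i, st in enumerate(scheme.rgb):
        y = i * row_h
        draw.rectangle([4, y + 4, 4 + sw, y + row_h - 4], fill=scheme.rgb[st])
        draw.text(
            (4 + sw + 8, y + 5),
            f"{st}  {scheme.names[st]}  {STATION_NAMES[st]}",
            fill=(0, 0, 0),
        )
    img.save(path)


def convert_structure_files(paths: list[str | Path]) -> list[LNcRecord]:
    """Extension point: consolidate per-structure coordinate exports.

    Planning workstations export one coordinate file per contoured structure;
    this package consumes a single consolidated CSV instead.  Implement this
    converter for your workstation's export format and feed its output to
    :func:`write_lnc_table`.
    """
    raise NotImplementedError(
        "per-structure export conversion is workstation-specific; "
        "build records directly and use write_lnc_table"
    )
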