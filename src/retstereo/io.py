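"""External formats: delimited site/cell tables, GeoJSON outlines, reports.

All text formats are UTF-8, comma-delimited with dot decimals.  Files written
by the pipeline carry provenance comment lines (``# key: value``) recording
the software version, config hash and seed.  Round-trips are lossless at
float repr precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping, shape

from . import __version__
from .fractionator import CountingSite
from .synthetic import CELL_TYPES, CellMap, RetinaOutline

__all__ = [
    "config_hash", "provenance_lines",
    "write_cellmap", "load_cellmap",
    "write_site_table", "load_site_table",
    "write_outline", "load_outline",
    "write_report",
]

SITE_COLUMNS = ["site_id", "x_mm", "y_mm", "frame_side_mm", "clipped_area_mm2",
                "stratum", "status"] + [f"count_{t}" for t in CELL_TYPES]


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_lines(seed: int | None = None, cfg_hash: str | None = None,
                     **extra: object) -> list[str]:
    lines = [f"# retstereo_version: {__version__}"]
    if cfg_hash is not None:
        lines.append(f"# config_hash: {cfg_hash}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    for k, v in extra.items():
        lines.append(f"# {k}: {v}")
    return lines


def _write_csv(path: Path, df: pd.DataFrame, header_lines: list[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        df.to_csv(fh, index=False)


def write_cellmap(path: str | Path, cellmap: CellMap, **provenance: object) -> None:
    df = pd.DataFrame({"x_mm": cellmap.x, "y_mm": cellmap.y,
                       "cell_type": cellmap.cell_type})
    provenance.setdefault("seed", cellmap.seed)
    _write_csv(Path(path), df, provenance_lines(**provenance))


def load_cellmap(path: str | Path, outline: RetinaOutline) -> CellMap:
    seed = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# seed:"):
                seed = int(line.split(":", 1)[1])
    df = pd.read_csv(path, comment="#")
    bad = set(df["cell_type"]) - set(CELL_TYPES)
    if bad:
        raise ValueError(f"unknown cell types in {path}: {sorted(bad)}")
    return CellMap(df["x_mm"].to_numpy(float), df["y_mm"].to_numpy(float),
                   df["cell_type"].to_numpy(object), outline, seed)


def sites_to_frame(sites: list[CountingSite]) -> pd.DataFrame:
    rows = []
    for s in sites:
        row = {"site_id": s.site_id, "x_mm": s.center[0], "y_mm": s.center[1],
               "frame_side_mm": s.frame_side, "clipped_area_mm2": s.clipped_area,
               "stratum": s.stratum, "status": s.status}
        for t in CELL_TYPES:
            row[f"count_{t}"] = s.counts.get(t, 0) if s.status != "omitted" else 0
        rows.append(row)
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def write_site_table(path: str | Path, sites: list[CountingSite],
                     **provenance: object) -> None:
    _write_csv(Path(path), sites_to_frame(sites), provenance_lines(**provenance))


def load_site_table(path: str | Path) -> list[CountingSite]:
    """Read a counting-site table; malformed rows raise with their line number."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in SITE_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    n_comment = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                n_comment += 1
            else:
                break
    sites = []
    for idx, row in df.iterrows():
        lineno = n_comment + 2 + int(idx)  # 1-based, after header
        counts = {}
        for t in CELL_TYPES:
            col = f"count_{t}"
            if col in df.columns:
                q = row[col]
                if pd.isna(q):
                    q = 0
                if q < 0 or q != int(q):
                    raise ValueError(
                        f"{path} line {lineno}: invalid count {q!r} for {t}")
                if int(q):
                    counts[t] = int(q)
        status = str(row["status"])
        if status not in ("ok", "single_imputed", "omitted"):
            raise ValueError(f"{path} line {lineno}: unknown status {status!r}")
        sites.append(CountingSite(
            site_id=int(row["site_id"]),
            center=(float(row["x_mm"]), float(row["y_mm"])),
            frame_side=float(row["frame_side_mm"]), clipped_frame=None,
            clipped_area=float(row["clipped_area_mm2"]),
            stratum=str(row["stratum"]),
            counts={} if status == "omitted" else counts, status=status))
    return sites


def write_outline(path: str | Path, outline: RetinaOutline,
                  **provenance: object) -> None:
    poly = Polygon(outline.boundary.exterior.coords,
                   [h.exterior.coords for h in outline.holes])
    gj = {"type": "Feature", "geometry": mapping(poly),
          "properties": {"eye_side": outline.eye_side,
                         "antero_posterior_diameter_mm": outline.axes[0],
                         "dorso_ventral_diameter_mm": outline.axes[1],
                         **{k: str(v) for k, v in provenance.items()}}}
    Path(path).write_text(json.dumps(gj), encoding="utf-8")


def load_outline(path: str | Path) -> RetinaOutline:
    gj = json.loads(Path(path).read_text(encoding="utf-8"))
    geom = shape(gj["geometry"])
    props = gj.get("properties", {})
    boundary = Polygon(geom.exterior.coords)
    holes = tuple(Polygon(ring.coords) for ring in geom.interiors)
    return RetinaOutline(
        boundary=boundary, holes=holes,
        eye_side=props.get("eye_side", "left"),
        axes=(float(props.get("antero_posterior_diameter_mm",
                              boundary.bounds[2] - boundary.bounds[0])),
              float(props.get("dorso_ventral_diameter_mm",
                              boundary.bounds[3] - boundary.bounds[1]))))


def write_report(path: str | Path, report: dict, **provenance: object) -> None:
    payload = {"provenance": {"retstereo_version": __version__,
                              **{k: str(v) for k, v in provenance.items()}},
               **report}
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify),
                          encoding="utf-8")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_map_text(path: str | Path, dmap, **provenance: object) -> None:
    """Plain-matrix text export of a density map (NaN outside the mask)."""
    header = provenance_lines(**provenance) + [
        f"# cell_type: {dmap.cell_type}",
        f"# resolution_mm: {dmap.resolution}",
        f"# extent: {dmap.extent}",
        f"# interpolation: {dmap.interpolation}",
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, dmap.raster, fmt="%.4f")
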