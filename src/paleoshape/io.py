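"""Readers and writers for the on-disk formats.

Supported formats
-----------------
* TPS-dialect landmark files: ``LM=<k>`` / ``LM3=<k>`` blocks of
  whitespace-separated coordinates, with ``ID=`` and ``SCALE=``
  records.  ``SCALE`` is applied only on request (default off), the
  community-standard behaviour.
* Long-format landmark CSV: ``specimen_id, landmark_label, x, y[, z],
  missing`` — one row per landmark.
* Template YAML: labels, bilateral pairs, midline, curve sections.
* Raw EDJ curve CSV: ``specimen, structure, point_index, x, y, z,
  anchor_label``.
* Outline CSV: ``specimen_id, vertex_index, x, y, side, group``.
* Demagnetization CSV: ``specimen_id, height, site_lat, site_lon,
  step_level, step_unit, x, y, z``.

All CSVs are comma-separated UTF-8 with a header row and '.' decimals;
coordinates and heights are carried through without unit conversion.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .landmarks import LandmarkSet, TemplateDef
from .magstrat import DemagSpecimen
from .outline import OutlinePolygon
from .ridge import RidgeCurveRaw

__all__ = [
    "read_tps_file",
    "write_tps_file",
    "read_landmark_csv",
    "write_landmark_csv",
    "read_template_yaml",
    "write_template_yaml",
    "read_outline_csv",
    "write_outline_csv",
    "read_demag_csv",
    "write_demag_csv",
    "write_manifest",
]


# ---------------------------------------------------------------------------
# TPS dialect

def read_tps_file(path: str | Path, apply_scale: bool = False,
                  template_id: str = "") -> list[LandmarkSet]:
    """Parse a TPS-dialect landmark file into LandmarkSets.

    Blocks start with ``LM=<k>`` (2D) or ``LM3=<k>`` (3D), followed by
    k coordinate lines, then optional ``ID=`` and ``SCALE=`` records.
    With ``apply_scale`` the coordinates are multiplied by the block's
    SCALE factor.  Missing landmarks encoded as the conventional
    ``-999 -999 [-999]`` sentinel get their missing flag set.
    """
    path = Path(path)
    out: list[LandmarkSet] = []
    block_pts: list[list[float]] = []
    block_dim = 0
    expected = -1
    block_id: str | None = None
    scale: float | None = None
    start_line = 0

    def flush(line_no: int) -> None:
        nonlocal block_pts, block_dim, expected, block_id, scale
        if expected < 0:
            return
        if len(block_pts) != expected:
            raise ValueError(
                f"{path}:{start_line}: LM block declares {expected} "
                f"landmarks but {len(block_pts)} were read")
        pts = np.asarray(block_pts, float) if block_pts else \
            np.zeros((0, block_dim))
        missing = np.all(pts == -999.0, axis=1) if len(pts) else \
            np.zeros(0, bool)
        pts = pts.copy()
        if apply_scale and scale is not None:
            pts[~missing] *= scale
        pts[missing] = np.nan
        sid = block_id if block_id is not None else f"specimen_{len(out)}"
        out.append(LandmarkSet(specimen_id=sid, points=pts,
                               missing=missing, template_id=template_id))
        block_pts, expected, block_id, scale = [], -1, None, None

    with path.open(encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3=") or upper.startswith("LM="):
                flush(line_no)
                start_line = line_no
                block_dim = 3 if upper.startswith("LM3=") else 2
                try:
                    expected = int(line.split("=", 1)[1])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{line_no}: malformed LM record "
                        f"{line!r}") from exc
            elif upper.startswith("ID="):
                block_id = line.split("=", 1)[1].strip()
            elif upper.startswith("SCALE="):
                try:
                    scale = float(line.split("=", 1)[1])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{line_no}: malformed SCALE record") from exc
            elif upper.startswith("IMAGE=") or upper.startswith("CURVES="):
                continue
            else:
                parts = line.split()
                if expected < 0 or len(parts) != block_dim:
                    raise ValueError(
                        f"{path}:{line_no}: unexpected line {line!r}")
                try:
                    block_pts.append([float(v) for v in parts])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{line_no}: non-numeric coordinate in "
                        f"{line!r}") from exc
    flush(-1)
    return out


def write_tps_file(path: str | Path, specimens: list[LandmarkSet],
                   scales: dict[str, float] | None = None) -> None:
    """Write LandmarkSets as a TPS-dialect file (round-trips with the
    reader)."""
    path = Path(path)
    lines: list[str] = []
    for s in specimens:
        tag = "LM3" if s.dim == 3 else "LM"
        lines.append(f"{tag}={s.n_landmarks}")
        for i in range(s.n_landmarks):
            if s.missing[i]:
                lines.append(" ".join(["-999"] * s.dim))
            else:
                lines.append(" ".join(f"{v:.12g}" for v in s.points[i]))
        lines.append(f"ID={s.specimen_id}")
        if scales and s.specimen_id in scales:
            lines.append(f"SCALE={scales[s.specimen_id]:.12g}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# landmark CSV

def write_landmark_csv(path: str | Path, specimens: list[LandmarkSet],
                       labels: list[str] | None = None) -> None:
    rows = []
    for s in specimens:
        lab = labels if labels is not None else [f"lm{i}" for i in
                                                 range(s.n_landmarks)]
        for i in range(s.n_landmarks):
            row = {"specimen_id": s.specimen_id, "landmark_label": lab[i],
                   "x": s.points[i, 0], "y": s.points[i, 1]}
            if s.dim == 3:
                row["z"] = s.points[i, 2]
            row["missing"] = int(s.missing[i])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_landmark_csv(path: str | Path,
                      template_id: str = "") -> list[LandmarkSet]:
    df = pd.read_csv(path)
    dim = 3 if "z" in df.columns else 2
    cols = ["x", "y", "z"][:dim]
    out = []
    for sid, grp in df.groupby("specimen_id", sort=False):
        pts = grp[cols].to_numpy(float)
        missing = grp["missing"].to_numpy().astype(bool) if "missing" in grp \
            else np.zeros(len(grp), bool)
        pts[missing] = np.nan
        out.append(LandmarkSet(specimen_id=str(sid), points=pts,
                               missing=missing, template_id=template_id))
    return out


# ---------------------------------------------------------------------------
# templates

def write_template_yaml(path: str | Path, tpl: TemplateDef) -> None:
    data = {
        "template_id": tpl.template_id,
        "dim": tpl.dim,
        "landmark_labels": list(tpl.landmark_labels),
        "bilateral_pairs": [list(p) for p in tpl.bilateral_pairs],
        "midline": list(tpl.midline),
        "curve_sections": [
            {"start": a, "end": b, "n_semilandmarks": n, "closed": bool(c)}
            for a, b, n, c in tpl.curve_sections],
        "surface_patches": [list(p) for p in tpl.surface_patches],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False),
                          encoding="utf-8")


def read_template_yaml(path: str | Path) -> TemplateDef:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    known = {"template_id", "dim", "landmark_labels", "bilateral_pairs",
             "midline", "curve_sections", "surface_patches"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown template keys: {sorted(unknown)}")
    return TemplateDef(
        template_id=data["template_id"],
        dim=int(data["dim"]),
        landmark_labels=list(data["landmark_labels"]),
        bilateral_pairs=[tuple(p) for p in data.get("bilateral_pairs", [])],
        midline=list(data.get("midline", [])),
        curve_sections=[(s["start"], s["end"], s["n_semilandmarks"],
                         bool(s["closed"]))
                        for s in data.get("curve_sections", [])],
        surface_patches=[list(p) for p in data.get("surface_patches", [])],
    )


# ---------------------------------------------------------------------------
# outlines

def write_outline_csv(path: str | Path,
                      outlines: list[OutlinePolygon]) -> None:
    rows = []
    for o in outlines:
        for i, (x, y) in enumerate(o.vertices):
            rows.append({"specimen_id": o.specimen_id, "vertex_index": i,
                         "x": x, "y": y, "side": o.side,
                         "group": o.group_label or ""})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_outline_csv(path: str | Path) -> list[OutlinePolygon]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for sid, grp in df.groupby("specimen_id", sort=False):
        grp = grp.sort_values("vertex_index")
        out.append(OutlinePolygon(
            specimen_id=str(sid),
            vertices=grp[["x", "y"]].to_numpy(float),
            side=str(grp["side"].iloc[0]),
            group_label=str(grp["group"].iloc[0]) or None))
    return out


# ---------------------------------------------------------------------------
# demagnetization records

def write_demag_csv(path: str | Path, specimens: list[DemagSpecimen],
                    step_unit: str = "C") -> None:
    rows = []
    for s in specimens:
        for lvl, vec in zip(s.treatment_levels, s.vectors):
            rows.append({"specimen_id": s.specimen_id,
                         "height": s.stratigraphic_height,
                         "site_lat": s.site_latitude,
                         "site_lon": s.site_longitude,
                         "step_level": lvl, "step_unit": step_unit,
                         "x": vec[0], "y": vec[1], "z": vec[2]})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_demag_csv(path: str | Path) -> list[DemagSpecimen]:
    df = pd.read_csv(path)
    out = []
    for sid, grp in df.groupby("specimen_id", sort=False):
        grp = grp.sort_values("step_level")
        out.append(DemagSpecimen(
            specimen_id=str(sid),
            site_latitude=float(grp["site_lat"].iloc[0]),
            site_longitude=float(grp["site_lon"].iloc[0]),
            stratigraphic_height=float(grp["height"].iloc[0]),
            treatment_levels=grp["step_level"].to_numpy(float),
            vectors=grp[["x", "y", "z"]].to_numpy(float)))
    return out


# ---------------------------------------------------------------------------
# run manifests

def write_manifest(path: str | Path, config: dict, seed: int | None) -> None:
    """Resolved-config + seed + version manifest written by every run."""
    from . import __version__
    payload = {"config": config, "seed": seed, "version": __version__}
    Path(path).write_text(json.dumps(payload, indent=2, default=str),
                          encoding="utf-8")
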