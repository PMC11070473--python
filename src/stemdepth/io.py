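"""File I/O: 16-bit depth PNG, masks, PLY point clouds, batch manifests.

Depth rasters persist losslessly as single-channel 16-bit PNG with the
depth scale carried in the manifest or camera config (0 stays the invalid
sentinel).  Point clouds use PLY 1.0, ascii or binary-little-endian, with
xyz float vertices and optional uchar RGB.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .camera_geometry import CameraModel
from .exceptions import FormatError
from . import metrics as metrics_mod
from .measurement import measure_stem

__all__ = ["read_depth", "write_depth", "read_mask", "write_mask",
           "read_ply", "write_ply", "read_manifest", "run_pipeline"]


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

def write_depth(path, depth: np.ndarray) -> None:
    """Write a uint16 depth raster as 16-bit PNG (or .npy for raw arrays)."""
    depth = np.asarray(depth)
    if depth.dtype != np.uint16 or depth.ndim != 2:
        raise FormatError("depth raster must be a 2-D uint16 array")
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, depth)
    else:
        Image.fromarray(depth).save(path)


def read_depth(path, depth_scale: float = 0.001) -> tuple[np.ndarray, float]:
    """Read a 16-bit PNG or .npy depth raster; returns (raster, scale)."""
    path = Path(path)
    if path.suffix == ".npy":
        arr = np.load(path)
    else:
        img = Image.open(path)
        if img.mode not in ("I;16", "I;16B", "I"):
            raise FormatError(f"{path}: expected a 16-bit single-channel "
                              f"image, got mode {img.mode!r}")
        arr = np.asarray(img)
    arr = arr.astype(np.uint16) if arr.dtype != np.uint16 else arr
    if arr.ndim != 2:
        raise FormatError(f"{path}: depth raster must be single-channel")
    return arr, depth_scale


def write_mask(path, mask: np.ndarray) -> None:
    """Write a {0,1} mask as an 8-bit PNG with values {0, 255}."""
    Image.fromarray((np.asarray(mask).astype(bool) * 255).astype(np.uint8)).save(path)


def read_mask(path) -> np.ndarray:
    """Read an 8-bit mask PNG back to a {0,1} uint8 raster."""
    return (np.asarray(Image.open(path).convert("L")) > 127).astype(np.uint8)


def read_rgb(path) -> np.ndarray:
    """Read an 8-bit color image as an (H, W, 3) uint8 array."""
    return np.asarray(Image.open(path).convert("RGB"))


def write_rgb(path, rgb: np.ndarray) -> None:
    Image.fromarray(np.asarray(rgb, dtype=np.uint8)).save(path)


# ---------------------------------------------------------------------------
# point clouds
# ---------------------------------------------------------------------------

def write_ply(path, vertices: np.ndarray, colors: np.ndarray | None = None,
              binary: bool = False) -> None:
    """Write an xyz[+rgb] point cloud as PLY 1.0.

    Coordinates are stored as float32; colors, when given, as uchar RGB.
    """
    import trimesh

    vertices = np.asarray(vertices, dtype=np.float32).reshape(-1, 3)
    if len(vertices) == 0:
        # trimesh rejects empty geometry; emit a valid zero-vertex header
        header = ["ply",
                  "format " + ("binary_little_endian" if binary else "ascii") + " 1.0",
                  "element vertex 0",
                  "property float x", "property float y", "property float z",
                  "end_header", ""]
        Path(path).write_bytes("\n".join(header).encode("ascii"))
        return
    pc = trimesh.PointCloud(vertices, colors=colors)
    encoding = "binary_little_endian" if binary else "ascii"
    Path(path).write_bytes(pc.export(file_type="ply", encoding=encoding))


def read_ply(path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read an xyz[+rgb] PLY point cloud.

    Returns float32 (N, 3) vertices and uint8 (N, 3) colors or None.
    """
    import trimesh

    text = Path(path).read_bytes()
    if not text.startswith(b"ply"):
        raise FormatError(f"{path}: not a PLY file")
    if b"element vertex 0" in text.split(b"end_header")[0]:
        return np.empty((0, 3), dtype=np.float32), None
    try:
        loaded = trimesh.load(str(path), file_type="ply", process=False)
    except Exception as exc:  # trimesh raises assorted types on bad schema
        raise FormatError(f"{path}: unsupported PLY schema ({exc})") from exc
    vertices = np.asarray(loaded.vertices, dtype=np.float32)
    colors = None
    try:
        c = np.asarray(loaded.colors)
        if c.size:
            colors = c[:, :3].astype(np.uint8)
    except (AttributeError, TypeError, ValueError):
        pass
    return vertices, colors


# ---------------------------------------------------------------------------
# batch pipeline
# ---------------------------------------------------------------------------

def read_manifest(path) -> pd.DataFrame:
    """Read a batch manifest CSV.

    Columns: id, rgb_path, depth_path, camera_config [, roi, true_mm].
    ``roi`` is "lo:hi" as fractions of the stem bounding box.
    """
    df = pd.read_csv(path)
    required = {"id", "rgb_path", "depth_path", "camera_config"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    if df["id"].duplicated().any():
        raise FormatError("manifest ids must be unique")
    return df


def _parse_roi(text) -> tuple[float, float]:
    lo, hi = str(text).split(":")
    return float(lo), float(hi)


def run_pipeline(manifest: pd.DataFrame | str | Path,
                 out_dir: str | Path | None = None,
                 n_scanlines: int = 3) -> tuple[pd.DataFrame, dict | None]:
    """Measure every frame of a manifest; optionally write per-frame JSON.

    Frames are processed independently (failures are recorded and the
    batch continues).  When the manifest carries ``true_mm``, a metrics
    report over the successful frames is returned alongside the results
    table, mirroring the field evaluation.

    Returns ``(results, report_dict_or_None)``; results columns are id,
    diameter_mm, n_scanlines_ok, roi, status [, true_mm, abs_err_mm].
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)
    if manifest.empty:
        warnings.warn("empty manifest; nothing to measure")
        return pd.DataFrame(columns=["id", "diameter_mm", "n_scanlines_ok",
                                     "roi", "status"]), None
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    cams: dict[str, CameraModel] = {}
    for rec in manifest.to_dict("records"):
        roi = _parse_roi(rec.get("roi", "0.55:0.80") or "0.55:0.80")
        cam_path = str(rec["camera_config"])
        if cam_path not in cams:
            cams[cam_path] = CameraModel.from_yaml(cam_path)
        row = {"id": rec["id"], "roi": f"{roi[0]}:{roi[1]}"}
        try:
            rgb = read_rgb(rec["rgb_path"])
            depth, _ = read_depth(rec["depth_path"],
                                  depth_scale=cams[cam_path].depth_scale)
            result = measure_stem(rgb, depth, cams[cam_path], roi=roi,
                                  n_scanlines=n_scanlines)
            row.update(diameter_mm=result.diameter_mm,
                       n_scanlines_ok=result.n_scanlines_ok, status="ok")
            if out_dir is not None:
                with open(out_dir / f"{rec['id']}.json", "w") as fh:
                    json.dump(result.to_dict(), fh, indent=2)
        except Exception as exc:  # per-frame isolation is the contract
            row.update(diameter_mm=np.nan, n_scanlines_ok=0,
                       status=f"failed: {exc}")
        if "true_mm" in rec and rec.get("true_mm") == rec.get("true_mm"):
            row["true_mm"] = float(rec["true_mm"])
            row["abs_err_mm"] = abs(row["diameter_mm"] - row["true_mm"]) \
                if row["status"] == "ok" else np.nan
        rows.append(row)

    results = pd.DataFrame(rows)
    report = None
    if "true_mm" in results.columns:
        ok = results[results["status"] == "ok"]
        if len(ok) >= 2:
            report = metrics_mod.evaluate((ok["diameter_mm"].to_numpy(),
                                           ok["true_mm"].to_numpy())).to_dict()
    if out_dir is not None:
        results.to_csv(out_dir / "results.csv", index=False)
        if report is not None:
            with open(out_dir / "metrics.json", "w") as fh:
                json.dump(report, fh, indent=2)
    return results, report
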