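"""Analytic RGB-D renderer of cylinder-stem scenes with exact ground truth.

A maize stem is modeled as a right circular cylinder of known radius in
front of a farther background plane, viewed by the two-camera RGB-D model
of :mod:`stemdepth.camera_geometry`.  Depth is ray-cast per pixel in the
depth camera (nearest-surface Z, optionally quantized to depth units and
perturbed by Gaussian noise), color is rendered on the color camera's
grid, and every ground-truth quantity the pipeline can be checked against
— silhouette, per-row width, projected axis, surface point cloud — is
computed analytically from the same geometry.

The default scene emulates the field acquisition geometry: an 848x480
sensor about 0.6 m from the stem, pitched roughly 45 degrees downward, so
the stem axis is strongly inclined out of the image plane but projects
nearly vertically.  Everything is deterministic for a fixed spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import hsv2rgb

from .camera_geometry import CameraModel, Extrinsics, Intrinsics, project, Point3D
from .exceptions import GeometryError

__all__ = ["SceneSpec", "SceneTruth", "RenderedScene", "render",
           "fixture_suite", "make_default_camera"]


def make_default_camera() -> CameraModel:
    """Plausible 848x480 RGB-D camera model used by the fixture scenes.

    The numbers are illustrative defaults in the realistic range for a
    small-baseline active-stereo sensor (color focal ~615 px, depth focal
    ~425 px, ~15 mm x-baseline, millimeter depth units); real deployments
    load their own calibration from config.
    """
    return CameraModel(
        color=Intrinsics(fx=615.0, fy=615.0, cx=424.0, cy=240.0,
                         width=848, height=480),
        depth=Intrinsics(fx=425.0, fy=425.0, cx=424.0, cy=240.0,
                         width=848, height=480),
        depth_to_color=Extrinsics(np.eye(3), np.array([0.0148, 0.0, 0.0]),
                                  src_frame="depth", dst_frame="color"),
        depth_scale=0.001,
    )


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic stem scene (depth-camera frame)."""

    radius_mm: float = 12.5
    axis_point: tuple[float, float, float] = (0.0, 0.0, 0.6)
    axis_direction: tuple[float, float, float] = (0.0, 0.7071067811865476,
                                                  0.7071067811865476)
    half_length_m: float = 0.6
    stem_hsv: tuple[float, float, float] = (70.0, 0.55, 0.55)   # H deg, S, V
    background_hsv: tuple[float, float, float] = (20.0, 0.45, 0.45)
    background_distance_m: float = 1.5
    cam: CameraModel = field(default_factory=make_default_camera)
    depth_noise_mm: float = 0.0
    depth_quantize: bool = True
    color_noise_sd: float = 3.0       # 8-bit counts
    seed: int = 0

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise GeometryError("radius must be positive")
        d = np.asarray(self.axis_direction, dtype=float)
        if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-9):
            raise GeometryError("axis_direction must be a unit vector")
        dx, dy = d[0], d[1]
        in_plane = np.degrees(np.arctan2(abs(dx), abs(dy))) if (dx, dy) != (0, 0) else 0.0
        if in_plane > 30.0 + 1e-9:
            raise GeometryError("axis must project near-vertically "
                                "(|image-plane inclination| <= 30 degrees)")


@dataclass
class SceneTruth:
    """Exact ground truth of a rendered scene, on the color grid."""

    diameter_mm: float
    silhouette: np.ndarray             # bool (H, W), color grid
    row_width_px: np.ndarray           # float (H,), 0 where no stem
    axis_col_by_row: np.ndarray        # float (H,), nan where no stem
    cloud: np.ndarray                  # (N, 3) float32, viewer depth frame
    axis_point: np.ndarray             # depth frame, meters
    axis_direction: np.ndarray


@dataclass
class RenderedScene:
    """Renderer output: rasters, point cloud and ground truth."""

    spec: SceneSpec
    rgb: np.ndarray                    # uint8 (H, W, 3), color grid
    depth: np.ndarray                  # uint16 (H, W), depth grid, depth units
    cloud: np.ndarray                  # (N, 3) float32, viewer depth frame
    cloud_colors: np.ndarray           # (N, 3) uint8
    truth: SceneTruth


def _pixel_rays(intr: Intrinsics) -> np.ndarray:
    cols, rows = np.meshgrid(np.arange(intr.width), np.arange(intr.height))
    return np.stack([(cols - intr.cx) / intr.fx,
                     (rows - intr.cy) / intr.fy,
                     np.ones_like(cols, dtype=float)], axis=-1)


def _ray_cylinder(intr: Intrinsics, a: np.ndarray, d: np.ndarray,
                  radius_m: float, half_len: float) -> np.ndarray:
    """Per-pixel Z of the nearest cylinder intersection; nan where missed."""
    v = _pixel_rays(intr)
    vd = v @ d
    vv = v - vd[..., None] * d
    ad = float(a @ d)
    aa = a - ad * d
    A = np.einsum("...i,...i", vv, vv)
    B = -2.0 * (vv @ aa)
    C = float(aa @ aa) - radius_m ** 2
    disc = B ** 2 - 4.0 * A * C
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (-B - np.sqrt(disc)) / (2.0 * A)
        s = t * vd - ad
    hit = (disc > 0) & (A > 1e-12) & (t > 0) & (np.abs(s) <= half_len)
    z = np.where(hit, t, np.nan)       # rays have v_z = 1, so Z = t
    return z


def _hsv_to_u8(hsv: tuple[float, float, float]) -> np.ndarray:
    h, s, v = hsv
    rgb = hsv2rgb(np.array([[[h / 360.0, s, v]]], dtype=float))[0, 0]
    return np.rint(rgb * 255.0).astype(np.uint8)


def render(spec: SceneSpec) -> RenderedScene:
    """Render one scene; deterministic for a fixed spec (seed included)."""
    cam = spec.cam
    a = np.asarray(spec.axis_point, dtype=float)
    d = np.asarray(spec.axis_direction, dtype=float)
    r_m = spec.radius_mm / 1000.0
    rng = np.random.default_rng(spec.seed)

    if a[2] <= 0:
        raise GeometryError("stem axis point must be in front of the camera")
    if a[2] + r_m >= spec.background_distance_m:
        raise GeometryError("background plane must be behind the stem")
    for intr, ext in ((cam.depth, None), (cam.color, cam.depth_to_color)):
        ap = a if ext is None else ext.apply(a)
        col, row = project(Point3D.from_array(ap, "x"), intr)
        if not (0 <= col < intr.width and 0 <= row < intr.height):
            raise GeometryError("stem axis point projects outside the frustum")

    # ---- depth raster (depth camera) --------------------------------------
    z_exact = _ray_cylinder(cam.depth, a, d, r_m, spec.half_length_m)
    stem_hit_d = np.isfinite(z_exact)
    z = np.where(stem_hit_d, z_exact, spec.background_distance_m)
    if spec.depth_noise_mm > 0:
        z = z + rng.normal(0.0, spec.depth_noise_mm / 1000.0, size=z.shape)
    units = z / cam.depth_scale
    units = np.rint(units) if spec.depth_quantize else units
    depth = np.clip(units, 1, np.iinfo(np.uint16).max).astype(np.uint16)

    # ---- point cloud of the visible stem surface (viewer depth frame) -----
    v_d = _pixel_rays(cam.depth)[stem_hit_d]
    pts = v_d * z_exact[stem_hit_d][..., None]
    cloud = (pts * np.array([1.0, -1.0, -1.0])).astype(np.float32)
    stem_rgb = _hsv_to_u8(spec.stem_hsv)
    cloud_colors = np.tile(stem_rgb, (len(cloud), 1))

    # ---- color raster (color camera) --------------------------------------
    ext = cam.depth_to_color
    a_c, d_c = ext.apply(a), ext.R @ d
    z_c = _ray_cylinder(cam.color, a_c, d_c, r_m, spec.half_length_m)
    silhouette = np.isfinite(z_c)
    bg_rgb = _hsv_to_u8(spec.background_hsv)
    rgb = np.where(silhouette[..., None], stem_rgb, bg_rgb).astype(float)
    if spec.color_noise_sd > 0:
        rgb = rgb + rng.normal(0.0, spec.color_noise_sd, size=rgb.shape)
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    # ---- analytic truth ----------------------------------------------------
    h = cam.color.height
    row_width = np.zeros(h, dtype=float)
    axis_col = np.full(h, np.nan, dtype=float)
    any_rows = np.nonzero(silhouette.any(axis=1))[0]
    for rr in any_rows:
        cols = np.nonzero(silhouette[rr])[0]
        row_width[rr] = cols[-1] - cols[0] + 1
    svals = np.linspace(-spec.half_length_m, spec.half_length_m, 4096)
    axis_pts = a_c[None, :] + svals[:, None] * d_c[None, :]
    front = axis_pts[:, 2] > 0
    axis_pts = axis_pts[front]
    pc = np.stack([cam.color.fx * axis_pts[:, 0] / axis_pts[:, 2] + cam.color.cx,
                   cam.color.fy * axis_pts[:, 1] / axis_pts[:, 2] + cam.color.cy],
                  axis=-1)
    order = np.argsort(pc[:, 1])
    axis_col[any_rows] = np.interp(any_rows, pc[order, 1], pc[order, 0])

    truth = SceneTruth(diameter_mm=2.0 * spec.radius_mm, silhouette=silhouette,
                       row_width_px=row_width, axis_col_by_row=axis_col,
                       cloud=cloud, axis_point=a, axis_direction=d)
    return RenderedScene(spec=spec, rgb=rgb, depth=depth, cloud=cloud,
                         cloud_colors=cloud_colors, truth=truth)


def fixture_suite(seed: int = 0, n_scenes: int = 20,
                  depth_noise_mm: float = 0.0) -> list[SceneSpec]:
    """The standard batch of test scenes spanning the field conditions.

    Diameters sweep 17-41 mm (the field tables' range), stem distances
    0.45-0.9 m, camera pitch 35-55 degrees (around the 45-degree rig
    geometry) and in-image inclinations up to 10 degrees, as upright field
    stems present.  Scene order and pose assignments derive from ``seed``
    only, so the suite is fully reproducible.
    """
    rng = np.random.default_rng(seed)
    diameters = np.linspace(17.0, 41.0, n_scenes)
    distances = rng.permutation(np.linspace(0.45, 0.9, n_scenes))
    pitches = rng.uniform(35.0, 55.0, n_scenes)
    in_plane = rng.uniform(-10.0, 10.0, n_scenes)
    specs = []
    for i in range(n_scenes):
        th = np.radians(pitches[i])
        ph = np.radians(in_plane[i])
        d = np.array([np.sin(ph) * np.cos(th),
                      np.cos(ph) * np.cos(th),
                      np.sin(th)])
        specs.append(SceneSpec(
            radius_mm=diameters[i] / 2.0,
            axis_point=(0.0, 0.0, float(distances[i])),
            axis_direction=tuple(d / np.linalg.norm(d)),
            background_distance_m=float(distances[i]) + 0.6,
            depth_noise_mm=depth_noise_mm,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        ))
    return specs
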