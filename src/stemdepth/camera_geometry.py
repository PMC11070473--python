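"""Pinhole-camera geometry for RGB-D stem measurement.

The RGB-D sensor has two optical systems: a color camera and a (stereo)
depth camera, each an undistorted pinhole described by :class:`Intrinsics`,
related by a rigid :class:`Extrinsics` transform.  Depth rasters store Z in
integer units of ``depth_scale`` meters, with 0 marking invalid pixels.

Three coordinate frames appear in the measurement choreography and every
3-D point carries a frame tag so the bookkeeping is mechanically checked:

``"opencv"``
    the right-handed frame in which image-based back-projection naturally
    lands (x right, y down, z forward);
``"color"``
    the color-stream camera frame used by the vendor's point-cloud viewer,
    obtained from ``"opencv"`` by negating y and z;
``"depth"``
    the depth-stream camera frame, in which exported point clouds live,
    reached from ``"color"`` by the color-to-depth rigid transform.

Distances are invariant under every step (both the axis flip and the rigid
transform are isometries), which is what makes the final Euclidean diameter
independent of the frame it is evaluated in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .exceptions import (
    BehindCameraError,
    BoundsError,
    FrameMismatchError,
    InvalidDepthError,
    ShapeError,
)

__all__ = [
    "Intrinsics",
    "Extrinsics",
    "CameraModel",
    "Point3D",
    "backproject",
    "project",
    "flip_yz",
    "rigid_transform",
    "align_depth_to_color",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class Intrinsics:
    """Pinhole intrinsics: focal lengths and principal point in pixels."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")

    @property
    def shape(self) -> tuple[int, int]:
        """Raster shape as (height, width)."""
        return (self.height, self.width)


@dataclass(frozen=True, eq=False)
class Extrinsics:
    """Rigid transform ``p' = R p + t`` between two tagged camera frames."""

    R: np.ndarray
    t: np.ndarray
    src_frame: str = "depth"
    dst_frame: str = "color"

    def __eq__(self, other):
        if not isinstance(other, Extrinsics):
            return NotImplemented
        return (np.array_equal(self.R, other.R)
                and np.array_equal(self.t, other.t)
                and self.src_frame == other.src_frame
                and self.dst_frame == other.dst_frame)

    def __post_init__(self):
        R = np.asarray(self.R, dtype=float).reshape(3, 3)
        t = np.asarray(self.t, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("R is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=_ORTHO_TOL):
            raise ValueError("R is not a proper rotation (det != +1)")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "t", t)

    def inverse(self) -> "Extrinsics":
        """The exact inverse transform (R', t') = (Rᵀ, −Rᵀ t)."""
        return Extrinsics(self.R.T, -self.R.T @ self.t,
                          src_frame=self.dst_frame, dst_frame=self.src_frame)

    @staticmethod
    def identity(src_frame: str = "depth", dst_frame: str = "color") -> "Extrinsics":
        return Extrinsics(np.eye(3), np.zeros(3), src_frame, dst_frame)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        """Apply to an (..., 3) array of coordinates (no frame checking)."""
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ self.R.T + self.t


@dataclass(frozen=True)
class CameraModel:
    """Full RGB-D camera description: both intrinsics, extrinsics, depth scale."""

    color: Intrinsics
    depth: Intrinsics
    depth_to_color: Extrinsics
    depth_scale: float = 0.001  # meters per depth unit

    def __post_init__(self):
        if self.depth_scale <= 0:
            raise ValueError("depth_scale must be positive")

    @property
    def color_to_depth(self) -> Extrinsics:
        """Inverse extrinsics, derived so the pair is always consistent."""
        return self.depth_to_color.inverse()

    # -- config round-trip --------------------------------------------------

    def to_dict(self) -> dict:
        def intr(i: Intrinsics) -> dict:
            return {"fx": float(i.fx), "fy": float(i.fy),
                    "cx": float(i.cx), "cy": float(i.cy),
                    "width": int(i.width), "height": int(i.height)}

        return {
            "color": intr(self.color),
            "depth": intr(self.depth),
            "depth_to_color": {
                "R": [float(v) for v in self.depth_to_color.R.ravel()],
                "t": [float(v) for v in self.depth_to_color.t],
            },
            "depth_scale": float(self.depth_scale),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(
            color=Intrinsics(**d["color"]),
            depth=Intrinsics(**d["depth"]),
            depth_to_color=Extrinsics(
                np.asarray(d["depth_to_color"]["R"], dtype=float).reshape(3, 3),
                np.asarray(d["depth_to_color"]["t"], dtype=float),
                src_frame="depth", dst_frame="color",
            ),
            depth_scale=d["depth_scale"],
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CameraModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class Point3D:
    """A 3-D point in meters, tagged with the camera frame it lives in."""

    x: float
    y: float
    z: float
    frame: str

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @staticmethod
    def from_array(xyz: np.ndarray, frame: str) -> "Point3D":
        x, y, z = (float(v) for v in np.asarray(xyz, dtype=float))
        return Point3D(x, y, z, frame)


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def backproject(pixel: tuple[float, float], depth_m: float,
                intr: Intrinsics, frame: str = "opencv") -> Point3D:
    """Recover the 3-D point of a pixel from its depth.

    Pinhole back-projection: ``Z = d``, ``X = (x - cx) / fx * Z``,
    ``Y = (y - cy) / fy * Z``, with ``(x, y) = (col, row)`` 0-based and the
    pixel center at integer coordinates.

    Parameters
    ----------
    pixel : (col, row)
        Pixel coordinates, col along x.
    depth_m : float
        Depth in meters; must be positive.
    intr : Intrinsics
        Intrinsics of the camera the pixel belongs to.
    frame : str
        Frame tag for the returned point; defaults to ``"opencv"`` because
        image-based back-projection lands in the right-handed image frame.
    """
    col, row = pixel
    if depth_m <= 0:
        raise InvalidDepthError(f"depth must be positive, got {depth_m}")
    if not (0 <= col < intr.width and 0 <= row < intr.height):
        raise BoundsError(f"pixel {pixel} outside {intr.width}x{intr.height}")
    z = float(depth_m)
    x = (col - intr.cx) / intr.fx * z
    y = (row - intr.cy) / intr.fy * z
    return Point3D(x, y, z, frame)


def project(p: Point3D, intr: Intrinsics) -> tuple[float, float]:
    """Project a 3-D point to continuous pixel coordinates (col, row)."""
    if p.z <= 0:
        raise BehindCameraError(f"cannot project point with z={p.z}")
    col = intr.fx * p.x / p.z + intr.cx
    row = intr.fy * p.y / p.z + intr.cy
    return (col, row)


def flip_yz(p: Point3D) -> Point3D:
    """Negate the y and z axes, mapping the ``opencv`` frame to ``color``.

    The vendor viewer's color-stream frame differs from the right-handed
    image frame by this axis inversion; applying the flip twice restores
    the input.
    """
    if p.frame not in ("opencv", "color"):
        raise FrameMismatchError(f"flip_yz expects an opencv/color point, got {p.frame!r}")
    new_frame = "color" if p.frame == "opencv" else "opencv"
    return Point3D(p.x, -p.y, -p.z, new_frame)


def rigid_transform(p: Point3D, ext: Extrinsics) -> Point3D:
    """Apply ``p' = R p + t``, retagging the point to the destination frame."""
    if p.frame != ext.src_frame:
        raise FrameMismatchError(
            f"point in frame {p.frame!r} but extrinsics map "
            f"{ext.src_frame!r} -> {ext.dst_frame!r}")
    return Point3D.from_array(ext.apply(p.as_array()), ext.dst_frame)


def backproject_grid(depth_m: np.ndarray, intr: Intrinsics) -> np.ndarray:
    """Vectorized back-projection of a full depth raster (meters).

    Returns an (H, W, 3) array; rows with non-positive depth produce
    unspecified coordinates and must be masked by the caller.
    """
    h, w = depth_m.shape
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    z = depth_m
    x = (cols - intr.cx) / intr.fx * z
    y = (rows - intr.cy) / intr.fy * z
    return np.stack([x, y, z], axis=-1)


def align_depth_to_color(depth_img: np.ndarray, cam: CameraModel) -> np.ndarray:
    """Resample a depth raster onto the color camera's pixel grid.

    Each valid depth pixel is back-projected with the depth intrinsics,
    moved to the color frame by ``depth_to_color``, projected with the
    color intrinsics and splatted to the nearest color-grid pixel.  When
    several source pixels land on one target pixel the smallest Z wins
    (z-buffer).  Unfilled pixels stay 0; no hole filling is performed, so
    the aligned raster is sparse exactly where the two views disagree.

    Parameters
    ----------
    depth_img : (H, W) integer raster
        Depth in units of ``cam.depth_scale`` meters; 0 = invalid.
    cam : CameraModel

    Returns
    -------
    (H', W') raster of the same dtype on the color grid.
    """
    depth_img = np.asarray(depth_img)
    if depth_img.shape != cam.depth.shape:
        raise ShapeError(
            f"depth raster {depth_img.shape} does not match depth intrinsics "
            f"{cam.depth.shape}")
    valid = depth_img > 0
    out = np.zeros(cam.color.shape, dtype=depth_img.dtype)
    if not valid.any():
        return out

    z = depth_img[valid].astype(float) * cam.depth_scale
    rows, cols = np.nonzero(valid)
    x = (cols - cam.depth.cx) / cam.depth.fx * z
    y = (rows - cam.depth.cy) / cam.depth.fy * z
    pts = np.stack([x, y, z], axis=-1)
    pts_c = cam.depth_to_color.apply(pts)
    zc = pts_c[:, 2]
    front = zc > 0
    pts_c, zc = pts_c[front], zc[front]

    uc = np.rint(cam.color.fx * pts_c[:, 0] / zc + cam.color.cx).astype(int)
    vc = np.rint(cam.color.fy * pts_c[:, 1] / zc + cam.color.cy).astype(int)
    inb = (uc >= 0) & (uc < cam.color.width) & (vc >= 0) & (vc < cam.color.height)
    uc, vc, zc = uc[inb], vc[inb], zc[inb]
    if uc.size == 0:
        return out

    units = np.maximum(np.rint(zc / cam.depth_scale), 1).astype(np.int64)
    zbuf = np.full(cam.color.shape, np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(zbuf, (vc, uc), units)
    filled = zbuf != np.iinfo(np.int64).max
    out[filled] = zbuf[filled].astype(depth_img.dtype)
    return out
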