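"""Calibrated image containers and TIFF I/O.

All pixel coordinates are 0-based and address pixel centres; the first
anchor of every polyline is the proximal (ciliary-base) end.  Physical
units are micrometres throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


class AnnotationError(ValueError):
    """Raised when an annotation (line, box, point set) is invalid for an image."""


@dataclass
class PlaneImage:
    """A single 2D fluorescence plane with physical calibration.

    Parameters
    ----------
    pixels : ndarray, shape (ny, nx)
        Non-negative, finite intensities.
    pixel_size_um : float
        Physical size of one pixel (isotropic in x and y).
    channel_name : str
        Free-text channel label (e.g. ``"tz"``, ``"marker"``).
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("PlaneImage.pixels must be 2D (ny, nx)")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("PlaneImage.pixels must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("PlaneImage.pixels must be non-negative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class VolumeStack:
    """A 3D z-stack with xy pixel size and z step.

    Axes are ordered ``(z, y, x)``.  ``model_z_step_um`` is the finer step
    used when the stack is resampled for 3D compartment modelling.
    """

    voxels: np.ndarray
    pixel_size_um: float
    z_step_um: float
    model_z_step_um: float = 0.1
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("VolumeStack.voxels must be 3D (z, y, x)")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("VolumeStack.voxels must be finite")
        if np.any(self.voxels < 0):
            raise ValueError("VolumeStack.voxels must be non-negative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if not self.z_step_um > 0:
            raise ValueError("z_step_um must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_um3(self) -> float:
        return self.pixel_size_um ** 2 * self.z_step_um


@dataclass
class IntensityProfile:
    """A 1D fluorescence profile sampled uniformly along a line.

    Positions start at 0 and increase proximal -> distal.
    """

    positions_um: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions_um.ndim != 1 or self.values.ndim != 1:
            raise ValueError("profile arrays must be 1D")
        if self.positions_um.size != self.values.size:
            raise ValueError("positions and values must have equal length")
        if self.positions_um.size < 3:
            raise ValueError("profile needs at least 3 samples")
        steps = np.diff(self.positions_um)
        if np.any(steps <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.allclose(steps, steps[0], atol=1e-9, rtol=0):
            raise ValueError("positions must be uniformly spaced")
        if abs(self.positions_um[0]) > 1e-12:
            raise ValueError("positions must start at 0")

    @property
    def step_um(self) -> float:
        return float(self.positions_um[1] - self.positions_um[0])

    def __len__(self) -> int:
        return self.values.size


@dataclass
class Polyline:
    """An ordered open polyline in pixel coordinates.

    Points are ``(x, y)`` pairs; the first point is the proximal end
    (ciliary base) by convention.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("Polyline.points must have shape (n, 2)")
        if self.points.shape[0] < 2:
            raise ValueError("Polyline needs at least 2 anchor points")
        if self.arc_length_px() <= 0:
            raise ValueError("Polyline must have positive arc length")

    def arc_length_px(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    def sample(self, arc_positions_px: np.ndarray) -> np.ndarray:
        """Points ``(x, y)`` at the given arc-length positions (pixels)."""
        seg = np.diff(self.points, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        arc = np.asarray(arc_positions_px, dtype=float)
        x = np.interp(arc, cum, self.points[:, 0])
        y = np.interp(arc, cum, self.points[:, 1])
        return np.column_stack([x, y])

    def tangent(self, arc_position_px: float) -> np.ndarray:
        """Unit tangent of the segment containing the given arc position."""
        seg = np.diff(self.points, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        cum = np.cumsum(seg_len)
        i = int(np.searchsorted(cum, arc_position_px, side="right"))
        i = min(i, len(seg) - 1)
        return seg[i] / seg_len[i]


@dataclass
class PointSet:
    """2D landmark points plus the anatomical (anterior-posterior) axis."""

    points: np.ndarray
    axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 1 or self.points.shape[1] != 2:
            raise ValueError("PointSet.points must have shape (n, 2), n >= 1")
        self.axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(self.axis)
        if norm == 0:
            raise ValueError("axis direction must be nonzero")
        self.axis = self.axis / norm


# ---------------------------------------------------------------------------
# TIFF I/O with a JSON calibration sidecar
# ---------------------------------------------------------------------------

def write_plane(path: str | Path, image: PlaneImage) -> None:
    """Write a plane as TIFF plus a ``.json`` calibration sidecar."""
    path = Path(path)
    tifffile.imwrite(path, image.pixels.astype(np.float32))
    sidecar = {"pixel_size_um": image.pixel_size_um, "channel_name": image.channel_name}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_plane(path: str | Path) -> PlaneImage:
    path = Path(path)
    pixels = tifffile.imread(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return PlaneImage(pixels, meta["pixel_size_um"], meta.get("channel_name", ""))


def write_stack(path: str | Path, stack: VolumeStack) -> None:
    """Write a z-stack as a multi-page TIFF plus a ``.json`` sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.voxels.astype(np.float32))
    sidecar = {
        "pixel_size_um": stack.pixel_size_um,
        "z_step_um": stack.z_step_um,
        "model_z_step_um": stack.model_z_step_um,
        "channel_name": stack.channel_name,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_stack(path: str | Path) -> VolumeStack:
    path = Path(path)
    voxels = tifffile.imread(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return VolumeStack(
        voxels,
        meta["pixel_size_um"],
        meta["z_step_um"],
        meta.get("model_z_step_um", 0.1),
        meta.get("channel_name", ""),
    )
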