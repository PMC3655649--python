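"""Stage-camera coordinate fusion.

A marker's global position combines two coordinate systems: the reading of
the micro X-Y stage that carries the specimen (millimetres) and the marker's
location in the camera image (pixels). The camera axes are rotated by an
unknown angle theta_s_c with respect to the stage axes; the fusion rotates
camera coordinates by that angle, scales pixels to millimetres, and adds the
stage reading:

    global = stage + offset + pixel_scale * R(theta_s_c) @ camera

theta_s_c is measured by sweeping the stage along one of its axes while
imaging a marker: the marker's image positions trace a straight line whose
angle relative to the declared stage axis is theta_s_c. The line is fitted
by total least squares (symmetric in both camera coordinates, since neither
is error-free), and the angle is reported as an axial quantity in
(-pi/2, pi/2]. The sign convention ties the two operations together: tracks
synthesised at angle theta re-estimate to theta, and global coordinates
computed with the estimated angle are consistent with the sweep. On a
physical apparatus the sign must be checked once against a known stage
motion (the camera y-flip flag at ingest exists for the same reason).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import CalibrationDataError, ConfigurationError, InvalidObservationError
from .geometry import Point2D

__all__ = [
    "StageCameraObservation",
    "CalibrationParams",
    "rotation_matrix",
    "to_global",
    "estimate_theta",
    "combine_axis_estimates",
]


def rotation_matrix(theta: float) -> np.ndarray:
    """Standard counterclockwise 2D rotation matrix."""
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class StageCameraObservation:
    """One marker seen as a (stage reading, image position) pair before fusion."""

    stage_pos: tuple[float, float]
    camera_pos: tuple[float, float]
    marker_id: str = ""
    step_id: str = ""

    def __post_init__(self) -> None:
        coords = (*self.stage_pos, *self.camera_pos)
        if len(self.stage_pos) != 2 or len(self.camera_pos) != 2 or not all(
            np.isfinite(c) for c in coords
        ):
            raise InvalidObservationError(
                f"invalid observation stage={self.stage_pos} camera={self.camera_pos}"
            )


@dataclass(frozen=True)
class CalibrationParams:
    """Parameters fusing camera and stage coordinates.

    ``pixel_scale`` (mm per pixel) comes from a user-supplied reference
    distance; it is an explicit input, never estimated implicitly.
    ``camera_origin_offset`` defaults to zero because the method only ever
    uses differences of global positions, which are offset-invariant.
    """

    theta_s_c: float
    pixel_scale: float
    camera_origin_offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.theta_s_c) and -math.pi < self.theta_s_c <= math.pi):
            raise ConfigurationError(f"theta_s_c = {self.theta_s_c} not in (-pi, pi]")
        if not (np.isfinite(self.pixel_scale) and self.pixel_scale > 0):
            raise ConfigurationError(f"pixel_scale must be > 0, got {self.pixel_scale}")
        if len(self.camera_origin_offset) != 2 or not all(
            np.isfinite(c) for c in self.camera_origin_offset
        ):
            raise ConfigurationError(f"invalid camera_origin_offset {self.camera_origin_offset}")


def to_global(obs: StageCameraObservation, calib: CalibrationParams) -> Point2D:
    """Fuse one observation into a global coordinate (mm). Exact, no fitting."""
    g = (
        np.asarray(obs.stage_pos, float)
        + np.asarray(calib.camera_origin_offset, float)
        + calib.pixel_scale * rotation_matrix(calib.theta_s_c) @ np.asarray(obs.camera_pos, float)
    )
    return Point2D(float(g[0]), float(g[1]))


def _camera_array(track) -> np.ndarray:
    if isinstance(track, np.ndarray):
        return np.asarray(track, float)
    return np.array([np.asarray(o.camera_pos, float) for o in track])


def estimate_theta(track, axis: str = "x") -> float:
    """Estimate theta_s_c from a single-axis stage sweep.

    Parameters
    ----------
    track : sequence of StageCameraObservation, or (n, 2) array
        Camera positions of one marker recorded while the stage moves along
        the declared axis.
    axis : {'x', 'y'}
        Which stage axis the sweep followed.

    Returns
    -------
    float
        The angle (radians) of the total-least-squares line through the
        camera positions, measured counterclockwise from the declared axis
        and normalised to (-pi/2, pi/2].
    """
    if axis not in ("x", "y"):
        raise ConfigurationError(f"declared axis must be 'x' or 'y', got {axis!r}")
    pts = _camera_array(track)
    if pts.ndim != 2 or pts.shape[1] != 2 or not np.all(np.isfinite(pts)):
        raise CalibrationDataError("camera track must be a finite (n, 2) set of positions")
    if len(pts) < 2:
        raise CalibrationDataError(f"need >= 2 observations to fit a sweep line, got {len(pts)}")
    centered = pts - pts.mean(axis=0)
    if not np.any(centered):
        raise CalibrationDataError("camera positions are all identical; stage did not move")
    # total least squares: dominant right-singular vector of the centred cloud
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    angle = math.atan2(direction[1], direction[0])
    if axis == "y":
        angle -= 0.5 * math.pi
    return _wrap_axial(angle)


def estimate_theta_residual(track, axis: str = "x") -> float:
    """RMS perpendicular distance (px) of the camera track from its fitted line."""
    pts = _camera_array(track)
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    perp = centered @ vt[1]
    return float(np.sqrt(np.mean(perp**2)))


def combine_axis_estimates(estimates: Sequence[float]) -> float:
    """Average several per-axis theta estimates.

    Angles of undirected lines live on a half-circle, so the mean is taken
    in the doubled-angle representation (the circular mean of 2*theta),
    which is well defined near the +-pi/2 wrap.
    """
    if len(estimates) == 0:
        raise CalibrationDataError("no theta estimates to combine")
    s = sum(math.sin(2.0 * t) for t in estimates)
    c = sum(math.cos(2.0 * t) for t in estimates)
    return _wrap_axial(0.5 * math.atan2(s, c))


def _wrap_axial(a: float) -> float:
    a = (a + 0.5 * math.pi) % math.pi - 0.5 * math.pi
    if a == -0.5 * math.pi:
        a = 0.5 * math.pi
    return a
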