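"""Ground-truth synthetic data: deformations, sweeps, spot images, recovery studies.

This module stands in for the physical experiment (a soft hydrogel strip
under stepwise uniaxial tension, imaged through a microscope). Its core
assumption is that the specimen deforms homogeneously between the four
markers, so the deformed marker positions are an affine image of the
initial ones:

    deformed = R(post_rotation) @ [R(theta) @ diag(1 - nu*eps, 1 + eps) @ R(theta)^T] @ v
               + translation + noise

where eps is the axial strain applied along a material axis tilted by theta
from the global y-axis (the misalignment the method is designed to
tolerate), nu couples the transverse contraction (the definition of
Poisson's ratio; no out-of-plane strain is simulated since the method is
2D), post_rotation is a rigid rotation acquired DURING deformation, and
noise is iid Gaussian on marker coordinates representing centroiding error.

With zero noise and zero post-rotation, the small-strain pipeline recovers
(eps, -nu*eps) as principal strains exactly; with a post-rotation, only the
rotation-invariant measures (green_lagrange, biot) recover nu.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage import measure as _skmeasure

from .calibration import StageCameraObservation, rotation_matrix
from .errors import (
    ConfigurationError,
    FieldOfViewError,
    GenerationError,
    NoMarkerError,
    QuadPoissonError,
)
from .geometry import DeformationPair, MarkerQuad, Point2D
from .poisson import EvalConfig, evaluate_step, naive_poisson

__all__ = [
    "DeformationScenario",
    "SpotImageParams",
    "DetectedSpot",
    "make_quad",
    "stretch_matrix",
    "apply_deformation",
    "sweep_track",
    "render_spots",
    "detect_centroids",
    "match_markers",
    "recovery_experiment",
]


@dataclass(frozen=True)
class DeformationScenario:
    """Parameters of one homogeneous stretch applied to a marker quad.

    axial_strain       engineering strain along the stretch axis (> -1)
    nu_true            ground-truth Poisson's ratio coupling the transverse axis
    material_axis_deg  tilt of the stretch axis from the global y-axis (deg);
                       this is the specimen/loading misalignment
    post_rotation_deg  rigid rotation acquired during deformation (deg)
    translation        rigid translation (mm)
    noise_sd           sd of additive Gaussian coordinate noise (mm)
    seed               seed for the noise stream
    """

    axial_strain: float
    nu_true: float
    material_axis_deg: float = 0.0
    post_rotation_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.axial_strain) or self.axial_strain <= -1.0:
            raise ConfigurationError(f"axial_strain must be > -1, got {self.axial_strain}")
        if not np.isfinite(self.noise_sd) or self.noise_sd < 0.0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass(frozen=True)
class SpotImageParams:
    """Rendering parameters for synthetic ink-spot marker images."""

    image_size: tuple[int, int] = (512, 512)  # (rows, cols)
    spot_sigma: float = 3.0                   # px
    peak_intensity: float = 1000.0            # grey levels above zero
    background: float = 100.0
    photon_noise_sd: float = 0.0
    pixel_scale: float = 0.05                 # mm per px

    def __post_init__(self) -> None:
        if self.spot_sigma <= 0:
            raise ConfigurationError("spot_sigma must be > 0")
        if self.peak_intensity <= self.background:
            raise ConfigurationError("peak_intensity must exceed background")
        if self.pixel_scale <= 0:
            raise ConfigurationError("pixel_scale must be > 0")


def make_quad(
    shape: str = "rectangle",
    size: float = 10.0,
    aspect: float = 0.3,
    seed: int | None = None,
    center: tuple[float, float] = (0.0, 0.0),
    max_tries: int = 100,
) -> MarkerQuad:
    """Generate a marker quadrilateral.

    'rectangle' returns an axis-aligned ``size x (aspect*size)`` rectangle
    centred at ``center`` — the footprint of a strip specimen's marked
    region. 'random_simple' samples four points uniformly in the same
    bounding box and resamples until they form a valid, not-too-thin simple
    quadrilateral (area at least 5% of the box).
    """
    if size <= 0:
        raise ConfigurationError(f"size must be > 0, got {size}")
    cx, cy = center
    if shape == "rectangle":
        hw, hh = 0.5 * size, 0.5 * aspect * size
        return MarkerQuad(
            [(cx - hw, cy - hh), (cx + hw, cy - hh), (cx + hw, cy + hh), (cx - hw, cy + hh)]
        )
    if shape != "random_simple":
        raise ConfigurationError(f"unknown shape {shape!r}; choose rectangle or random_simple")
    rng = np.random.default_rng(seed)
    box = np.array([size, aspect * size])
    for _ in range(max_tries):
        pts = (rng.random((4, 2)) - 0.5) * box + np.array([cx, cy])
        try:
            quad = MarkerQuad(pts)
        except QuadPoissonError:
            continue
        if quad.signed_area >= 0.05 * box[0] * box[1]:
            return quad
    raise GenerationError(f"no valid quadrilateral found in {max_tries} tries")


def stretch_matrix(scenario: DeformationScenario) -> np.ndarray:
    """Pure material stretch R(theta) diag(1 - nu*eps, 1 + eps) R(theta)^T."""
    theta = math.radians(scenario.material_axis_deg)
    r = rotation_matrix(theta)
    d = np.diag([1.0 - scenario.nu_true * scenario.axial_strain, 1.0 + scenario.axial_strain])
    return r @ d @ r.T


def apply_deformation(quad: MarkerQuad, scenario: DeformationScenario) -> DeformationPair:
    """Deform a quad per the scenario; noise is added to the deformed vertices."""
    a = rotation_matrix(math.radians(scenario.post_rotation_deg)) @ stretch_matrix(scenario)
    v = quad.vertices @ a.T + np.asarray(scenario.translation, float)
    if scenario.noise_sd > 0.0:
        rng = np.random.default_rng(scenario.seed)
        v = v + rng.normal(0.0, scenario.noise_sd, size=v.shape)
    return DeformationPair(quad, MarkerQuad(v, quad.labels))


def sweep_track(
    theta_deg: float,
    axis: str = "x",
    n: int = 20,
    span_px: float = 500.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> list[StageCameraObservation]:
    """Synthesise a stage-sweep calibration track.

    The stage moves along the declared axis while a marker is imaged; its
    camera positions trace a line at ``theta_deg`` from that axis. Optional
    Gaussian pixel noise perturbs both camera coordinates.
    """
    if axis not in ("x", "y"):
        raise ConfigurationError(f"axis must be 'x' or 'y', got {axis!r}")
    if n < 2:
        raise ConfigurationError("need n >= 2 sweep points")
    base = 0.0 if axis == "x" else 0.5 * math.pi
    ang = base + math.radians(theta_deg)
    t = np.linspace(-0.5 * span_px, 0.5 * span_px, n)
    cam = np.column_stack([t * math.cos(ang), t * math.sin(ang)])
    if noise_sd > 0.0:
        cam = cam + np.random.default_rng(seed).normal(0.0, noise_sd, size=cam.shape)
    stage = np.zeros_like(cam)
    stage[:, 0 if axis == "x" else 1] = t  # stage readings along the declared axis
    return [
        StageCameraObservation(
            stage_pos=(float(s[0]), float(s[1])),
            camera_pos=(float(c[0]), float(c[1])),
            marker_id="cal",
            step_id=f"sweep{i}",
        )
        for i, (s, c) in enumerate(zip(stage, cam))
    ]


def render_spots(
    markers: Sequence[Point2D] | np.ndarray,
    params: SpotImageParams = SpotImageParams(),
    seed: int | None = None,
) -> np.ndarray:
    """Render Gaussian ink-spot profiles at marker positions.

    Coordinates map as column = x/pixel_scale, row = y/pixel_scale; every
    marker must sit at least 3 sigma inside the field of view. Returns a
    float image (rows, cols) = background + sum of spots (+ noise).
    """
    pts = np.array(
        [m.as_array() if isinstance(m, Point2D) else np.asarray(m, float) for m in markers]
    )
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ConfigurationError("markers must be a sequence of 2D points")
    rows, cols = params.image_size
    px = pts / params.pixel_scale  # (x_px, y_px) = (col, row)
    margin = 3.0 * params.spot_sigma
    for (c, r), m in zip(px, pts):
        if not (margin <= c <= cols - 1 - margin and margin <= r <= rows - 1 - margin):
            raise FieldOfViewError(
                f"marker at ({m[0]:g}, {m[1]:g}) mm -> pixel ({c:.1f}, {r:.1f}) is within "
                f"{margin:g} px of the image border"
            )
    rr, cc = np.mgrid[0:rows, 0:cols]
    img = np.full((rows, cols), params.background, dtype=float)
    amp = params.peak_intensity - params.background
    for c, r in px:
        img += amp * np.exp(-((cc - c) ** 2 + (rr - r) ** 2) / (2.0 * params.spot_sigma**2))
    if params.photon_noise_sd > 0.0:
        img = img + np.random.default_rng(seed).normal(0.0, params.photon_noise_sd, size=img.shape)
    return img


@dataclass(frozen=True)
class DetectedSpot:
    """One detected marker: intensity-weighted centroid (mm) plus QC scores."""

    position: Point2D
    area_px: int
    quality: float  # minor/major axis ratio; ~1 for a round spot, low for merged blobs


def detect_centroids(
    image: np.ndarray,
    params: SpotImageParams = SpotImageParams(),
    threshold_frac: float = 0.5,
) -> list[DetectedSpot]:
    """Threshold, label, and centroid the spots in a marker image.

    The threshold sits at ``background + threshold_frac * (max - background)``;
    connected components (8-connectivity) become candidate spots whose
    intensity-weighted centroids are returned in mm, largest component
    first. The quality score is the minor/major inertia-axis ratio: two
    spots merged into one elongated component score well below a round
    single spot.
    """
    if not (0.0 < threshold_frac < 1.0):
        raise ConfigurationError(f"threshold_frac must be in (0, 1), got {threshold_frac}")
    img = np.asarray(image, float)
    peak = float(img.max())
    if peak <= params.background:
        raise NoMarkerError("image has no intensity above background")
    thresh = params.background + threshold_frac * (peak - params.background)
    mask = img > thresh
    labels = _skmeasure.label(mask, connectivity=2)
    props = _skmeasure.regionprops(labels, intensity_image=np.clip(img - params.background, 0, None))
    if not props:
        raise NoMarkerError("no connected component above threshold")
    props.sort(key=lambda p: p.area, reverse=True)
    spots = []
    for p in props:
        r, c = p.centroid_weighted
        major = p.axis_major_length
        quality = (p.axis_minor_length / major) if major > 0 else 1.0
        spots.append(
            DetectedSpot(
                position=Point2D(float(c) * params.pixel_scale, float(r) * params.pixel_scale),
                area_px=int(p.area),
                quality=float(quality),
            )
        )
    return spots


def match_markers(
    detected: Sequence[DetectedSpot], reference: Sequence[Point2D] | np.ndarray
) -> list[Point2D]:
    """Greedy nearest-neighbour assignment of detections to reference markers.

    Restores marker identity after detection (detections are sorted by size,
    not by identity). Each reference point takes its closest unused
    detection.
    """
    ref = np.array(
        [p.as_array() if isinstance(p, Point2D) else np.asarray(p, float) for p in reference]
    )
    det = np.array([s.position.as_array() for s in detected])
    if len(det) < len(ref):
        raise NoMarkerError(f"only {len(det)} detections for {len(ref)} reference markers")
    dists = np.linalg.norm(ref[:, None, :] - det[None, :, :], axis=2)
    used: set[int] = set()
    out: dict[int, Point2D] = {}
    for i in np.argsort(dists.min(axis=1)):  # most confident assignments first
        i = int(i)
        j = next(int(k) for k in np.argsort(dists[i]) if int(k) not in used)
        used.add(j)
        out[i] = detected[j].position
    return [out[i] for i in range(len(ref))]


def recovery_experiment(
    scenarios: Iterable[DeformationScenario],
    n_reps: int = 100,
    seed: int | None = None,
    base_quad: MarkerQuad | None = None,
    config: EvalConfig | None = None,
) -> pd.DataFrame:
    """Monte-Carlo bias/RMSE study of both estimators over a scenario grid.

    For each scenario, ``n_reps`` independent noise realisations are drawn
    (seeded reproducibly from ``seed``), the element and naive estimators
    are run on each, and per-scenario mean, bias (mean - nu_true), standard
    deviation, and RMSE of nu-hat are tabulated per method. Estimator
    failures (e.g. naive method at extreme noise) are counted, not raised.
    """
    scenarios = list(scenarios)
    if n_reps < 2:
        raise ConfigurationError("n_reps must be >= 2")
    if base_quad is None:
        base_quad = make_quad("rectangle", size=10.0, aspect=0.3)
    config = config or EvalConfig()
    child_seeds = np.random.SeedSequence(seed).generate_state(len(scenarios) * n_reps) % (2**31)
    rows = []
    for s_idx, scen in enumerate(scenarios):
        estimates: dict[str, list[float]] = {"element": [], "naive": []}
        failures = {"element": 0, "naive": 0}
        for rep in range(n_reps):
            rep_seed = int(child_seeds[s_idx * n_reps + rep])
            pair = apply_deformation(base_quad, replace(scen, seed=rep_seed))
            try:
                estimates["element"].append(evaluate_step(pair, config).nu)
            except QuadPoissonError:
                failures["element"] += 1
            try:
                estimates["naive"].append(naive_poisson(pair).nu)
            except QuadPoissonError:
                failures["naive"] += 1
        for method in ("element", "naive"):
            est = np.array(estimates[method])
            ok = est.size > 0
            rows.append(
                {
                    "axial_strain": scen.axial_strain,
                    "nu_true": scen.nu_true,
                    "material_axis_deg": scen.material_axis_deg,
                    "post_rotation_deg": scen.post_rotation_deg,
                    "noise_sd": scen.noise_sd,
                    "method": method,
                    "n_reps": n_reps,
                    "n_fail": failures[method],
                    "mean_nu": float(est.mean()) if ok else float("nan"),
                    "sd_nu": float(est.std(ddof=1)) if est.size > 1 else float("nan"),
                    "bias": float(est.mean() - scen.nu_true) if ok else float("nan"),
                    "rmse": float(np.sqrt(np.mean((est - scen.nu_true) ** 2))) if ok else float("nan"),
                }
            )
    return pd.DataFrame(rows)
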