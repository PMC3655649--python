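"""Principal strains, Poisson's ratio, and the stepwise evaluation procedure.

The method's central quantity is nu = -eps2/eps1, the negative ratio of the
minimum to maximum principal strain of the element. Because principal
strains are intrinsic to the deformation, the result is unaffected by any
rigid misalignment between specimen, loading axis, and camera — unlike the
traditional axis-projected estimator, which is also provided here as a
baseline (``naive_poisson``) precisely so that its misalignment bias can be
demonstrated and quantified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .element import StrainTensor2D, element_strain
from .errors import (
    ConfigurationError,
    NaiveMethodError,
    QuadPoissonError,
    UndeformedSpecimenError,
)
from .geometry import DeformationPair, MarkerQuad

__all__ = [
    "PrincipalStrains",
    "PoissonResult",
    "EvalConfig",
    "principal_strains",
    "poisson_ratio",
    "naive_poisson",
    "evaluate_step",
    "evaluate_sequence",
]

DEFAULT_TOL = 1e-6


@dataclass(frozen=True)
class PrincipalStrains:
    """Eigen-decomposition of a 2D strain tensor.

    ``angle`` is the direction of the maximum principal strain ``eps1``,
    counterclockwise from the global x-axis, normalised to (-pi/2, pi/2].
    """

    eps1: float
    eps2: float
    angle: float

    def __post_init__(self) -> None:
        if self.eps1 < self.eps2:
            raise ConfigurationError("eps1 must be >= eps2")


@dataclass(frozen=True)
class EvalConfig:
    """Knobs of the element pipeline (strain measure, evaluation mode, tolerance)."""

    measure: str = "small"
    mode: str = "centroid"
    tol: float = DEFAULT_TOL


@dataclass(frozen=True)
class PoissonResult:
    """Poisson's ratio and diagnostics for one deformation step."""

    nu: float
    principal: PrincipalStrains | None
    elongation_pct: float
    step_id: str | None = None
    method: str = "element"
    heterogeneity: float = float("nan")
    misalignment_rad: float = float("nan")
    warnings: tuple[str, ...] = ()
    status: str = "ok"
    message: str = ""

    @property
    def eps1(self) -> float:
        return self.principal.eps1 if self.principal else float("nan")

    @property
    def eps2(self) -> float:
        return self.principal.eps2 if self.principal else float("nan")

    @property
    def principal_angle_deg(self) -> float:
        return math.degrees(self.principal.angle) if self.principal else float("nan")

    @property
    def misalignment_deg(self) -> float:
        return math.degrees(self.misalignment_rad)


def principal_strains(t: StrainTensor2D) -> PrincipalStrains:
    """Closed-form eigen-decomposition of a symmetric 2x2 strain tensor.

    Mohr's-circle form: centre m = (exx + eyy)/2, radius
    r = sqrt(((exx - eyy)/2)^2 + exy^2), eps1 = m + r, eps2 = m - r,
    angle = atan2(2 exy, exx - eyy) / 2.
    """
    m = 0.5 * (t.exx + t.eyy)
    r = math.hypot(0.5 * (t.exx - t.eyy), t.exy)
    # atan2 returns (-pi, pi]; halving lands in (-pi/2, pi/2] as required
    angle = 0.5 * math.atan2(2.0 * t.exy, t.exx - t.eyy)
    return PrincipalStrains(eps1=m + r, eps2=m - r, angle=angle)


def poisson_ratio(p: PrincipalStrains, tol: float = DEFAULT_TOL) -> float:
    """nu = -eps2/eps1; undefined (error) when the specimen is undeformed."""
    if abs(p.eps1) <= tol:
        raise UndeformedSpecimenError(
            f"|eps1| = {abs(p.eps1):.3g} <= tol = {tol:g}: Poisson's ratio undefined at zero elongation"
        )
    return -p.eps2 / p.eps1


def _wrap_half_pi(a: float) -> float:
    """Wrap an axial (direction-of-a-line) angle into (-pi/2, pi/2]."""
    a = (a + 0.5 * math.pi) % math.pi - 0.5 * math.pi
    if a == -0.5 * math.pi:
        a = 0.5 * math.pi
    return a


def naive_poisson(
    pair: DeformationPair, tol: float = DEFAULT_TOL, step_id: str | None = None
) -> PoissonResult:
    """Axis-projected baseline estimator of Poisson's ratio.

    Assumes the loading axis is the global y-axis and that markers are
    measured from the loading-axis origin, so that each marker obeys
    ``yf = yi (1 + eps_y)`` and ``xf = xi (1 - eps_y nu)``. Per-marker axial
    strains and transverse ratios are averaged arithmetically over the four
    markers. This estimator intentionally reproduces the misalignment bias
    of the traditional method: when the stretch axis is tilted with respect
    to the global y-axis the returned nu is systematically wrong, which is
    exactly the failure mode the element method removes.
    """
    xi, yi = pair.initial.vertices[:, 0], pair.initial.vertices[:, 1]
    xf, yf = pair.deformed.vertices[:, 0], pair.deformed.vertices[:, 1]
    if np.any(np.abs(xi) <= tol) or np.any(np.abs(yi) <= tol):
        raise NaiveMethodError(
            "axis-projected method inapplicable: a marker's initial coordinate is "
            f"within tol = {tol:g} of a loading axis"
        )
    eps_y_per_marker = yf / yi - 1.0
    eps_y = float(np.mean(eps_y_per_marker))
    if abs(eps_y) <= tol:
        raise UndeformedSpecimenError(
            f"|eps_y| = {abs(eps_y):.3g} <= tol = {tol:g}: specimen undeformed"
        )
    nu = float(np.mean((1.0 - xf / xi) / eps_y))
    return PoissonResult(
        nu=nu,
        principal=None,
        elongation_pct=100.0 * eps_y,
        step_id=step_id,
        method="naive",
    )


def evaluate_step(
    pair: DeformationPair, config: EvalConfig | None = None, step_id: str | None = None
) -> PoissonResult:
    """Full element pipeline for one deformation step.

    Chains element strain -> principal strains -> nu = -eps2/eps1, and fills
    diagnostics: elongation (100 * eps1), strain-field heterogeneity, and the
    apparent misalignment (deviation of the maximum-principal-strain
    direction from the global y-axis, wrapped to (-pi/2, pi/2]).
    """
    config = config or EvalConfig()
    tensor, hetero = element_strain(pair, mode=config.mode, measure=config.measure)
    principal = principal_strains(tensor)
    nu = poisson_ratio(principal, tol=config.tol)
    warnings: tuple[str, ...] = ()
    if abs(principal.eps1 - principal.eps2) <= config.tol * max(1.0, abs(principal.eps1)):
        warnings = ("equibiaxial strain: principal direction undefined, nu = -1 by definition",)
    misalign = _wrap_half_pi(principal.angle - 0.5 * math.pi)
    return PoissonResult(
        nu=nu,
        principal=principal,
        elongation_pct=100.0 * principal.eps1,
        step_id=step_id,
        method="element",
        heterogeneity=hetero,
        misalignment_rad=misalign,
        warnings=warnings,
    )


def evaluate_sequence(
    initial: MarkerQuad,
    deformed_steps: Sequence[MarkerQuad],
    config: EvalConfig | None = None,
    step_ids: Sequence[str] | None = None,
) -> list[PoissonResult]:
    """Evaluate a stepwise elongation sweep.

    Every step is compared against the ORIGINAL initial configuration (total
    strain, not incremental), mirroring a protocol in which the specimen is
    repeatedly elongated and re-imaged while the reference image is taken
    once. Per-step failures (e.g. an undeformed first step) are recorded in
    the corresponding result's ``status``/``message`` instead of aborting
    the sweep.
    """
    if len(deformed_steps) == 0:
        raise ConfigurationError("at least one deformed step is required")
    if step_ids is None:
        step_ids = [f"step{i + 1}" for i in range(len(deformed_steps))]
    if len(step_ids) != len(deformed_steps):
        raise ConfigurationError("step_ids and deformed_steps lengths differ")
    results: list[PoissonResult] = []
    for sid, quad in zip(step_ids, deformed_steps):
        try:
            results.append(evaluate_step(DeformationPair(initial, quad), config, step_id=sid))
        except QuadPoissonError as exc:
            results.append(
                PoissonResult(
                    nu=float("nan"),
                    principal=None,
                    elongation_pct=float("nan"),
                    step_id=sid,
                    method="element",
                    status="error",
                    message=str(exc),
                )
            )
    return results
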