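"""First-order isoparametric quadrilateral kinematics.

The four global marker coordinates are treated as the nodes of a single
4-node plane element. Geometry and displacement are interpolated bilinearly
in natural coordinates (xi, eta) in [-1, 1]^2; the deformation gradient F
follows from the displacement gradient taken with respect to the initial
configuration through the inverse Jacobian. Because displacements are
prescribed at all four nodes, no material constants enter: the computation
is purely kinematic.

Strain measures
---------------
small          sym(F) - I          exact for infinitesimal strain; not
                                   invariant to rigid rotation *during*
                                   deformation.
green_lagrange (F^T F - I) / 2     invariant to rigid rotation of the
                                   deformed configuration.
biot           sqrt(F^T F) - I     principal values equal stretch - 1,
                                   i.e. engineering strain on principal axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DegenerateElementError
from .geometry import DeformationPair

__all__ = [
    "StrainTensor2D",
    "shape_functions",
    "shape_function_gradients",
    "deformation_gradient_at",
    "strain_at",
    "element_strain",
    "GAUSS_POINTS",
]

# corner signs (xi_k, eta_k) matching the counterclockwise vertex order
_CORNERS = np.array([[-1.0, -1.0], [1.0, -1.0], [1.0, 1.0], [-1.0, 1.0]])

#: 2x2 Gauss quadrature points (+-1/sqrt(3), +-1/sqrt(3)).
_G = 1.0 / np.sqrt(3.0)
GAUSS_POINTS: tuple[tuple[float, float], ...] = ((-_G, -_G), (_G, -_G), (_G, _G), (-_G, _G))

STRAIN_MEASURES = ("small", "green_lagrange", "biot")


@dataclass(frozen=True)
class StrainTensor2D:
    """Symmetric in-plane strain state.

    ``exy`` is the tensor shear component, i.e. half the engineering shear
    angle. ``measure`` records which strain definition produced it.
    """

    exx: float
    eyy: float
    exy: float
    measure: str = "small"

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.exx, self.eyy, self.exy])):
            raise ConfigurationError("non-finite strain components")

    def as_matrix(self) -> np.ndarray:
        return np.array([[self.exx, self.exy], [self.exy, self.eyy]])

    @classmethod
    def from_matrix(cls, m: np.ndarray, measure: str) -> "StrainTensor2D":
        m = np.asarray(m, float)
        return cls(float(m[0, 0]), float(m[1, 1]), float(0.5 * (m[0, 1] + m[1, 0])), measure)


def _check_natural(xi: float, eta: float) -> None:
    if not (np.isfinite(xi) and np.isfinite(eta) and abs(xi) <= 1.0 and abs(eta) <= 1.0):
        raise ConfigurationError(f"natural coordinates ({xi}, {eta}) outside [-1, 1]^2")


def shape_functions(xi: float, eta: float) -> np.ndarray:
    """Bilinear shape functions N_k(xi, eta) = (1 + xi_k xi)(1 + eta_k eta)/4.

    The four weights are a partition of unity and reproduce any affine
    function of position exactly (linear completeness).
    """
    _check_natural(xi, eta)
    return 0.25 * (1.0 + _CORNERS[:, 0] * xi) * (1.0 + _CORNERS[:, 1] * eta)


def shape_function_gradients(xi: float, eta: float) -> np.ndarray:
    """(4, 2) array of dN_k/dxi and dN_k/deta."""
    _check_natural(xi, eta)
    return 0.25 * np.column_stack(
        [
            _CORNERS[:, 0] * (1.0 + _CORNERS[:, 1] * eta),
            _CORNERS[:, 1] * (1.0 + _CORNERS[:, 0] * xi),
        ]
    )


def deformation_gradient_at(pair: DeformationPair, xi: float = 0.0, eta: float = 0.0) -> np.ndarray:
    """Deformation gradient F = I + du/dX at natural coordinates (xi, eta).

    du/dX is the gradient of the bilinearly interpolated vertex displacement
    field with respect to initial global coordinates, obtained by mapping
    natural-coordinate derivatives through the inverse Jacobian of the
    initial configuration. For an affine map between the two quads this is
    that map's linear part, independent of (xi, eta).
    """
    grads = shape_function_gradients(xi, eta)  # (4, 2)
    jac = pair.initial.vertices.T @ grads      # dX/d(xi, eta), (2, 2)
    det = float(np.linalg.det(jac))
    if det <= 0.0:
        raise DegenerateElementError(
            f"non-positive Jacobian determinant {det:g} at (xi, eta) = ({xi:g}, {eta:g})"
        )
    du_dnat = pair.displacements.T @ grads     # (2, 2)
    return np.eye(2) + du_dnat @ np.linalg.inv(jac)


def _strain_from_F(f: np.ndarray, measure: str) -> np.ndarray:
    if measure == "small":
        return 0.5 * (f + f.T) - np.eye(2)
    if measure == "green_lagrange":
        return 0.5 * (f.T @ f - np.eye(2))
    if measure == "biot":
        # right stretch tensor U = sqrt(F^T F) via eigendecomposition of C
        w, v = np.linalg.eigh(f.T @ f)
        u = (v * np.sqrt(np.maximum(w, 0.0))) @ v.T
        return u - np.eye(2)
    raise ConfigurationError(f"unknown strain measure {measure!r}; choose from {STRAIN_MEASURES}")


def strain_at(
    pair: DeformationPair, xi: float = 0.0, eta: float = 0.0, measure: str = "small"
) -> StrainTensor2D:
    """Strain tensor at one natural-coordinate location."""
    if measure not in STRAIN_MEASURES:
        raise ConfigurationError(f"unknown strain measure {measure!r}; choose from {STRAIN_MEASURES}")
    f = deformation_gradient_at(pair, xi, eta)
    return StrainTensor2D.from_matrix(_strain_from_F(f, measure), measure)


def element_strain(
    pair: DeformationPair, mode: str = "centroid", measure: str = "small"
) -> tuple[StrainTensor2D, float]:
    """Single representative strain of the element, plus a heterogeneity score.

    mode='centroid' evaluates at (xi, eta) = (0, 0); mode='gauss_mean'
    averages the tensor component-wise over the 2x2 Gauss points. The
    heterogeneity score is the maximum Frobenius distance between any Gauss
    point tensor and the centroid tensor: zero for a homogeneous (affine)
    deformation, positive when the bilinear field carries hourglass content,
    in which case the single-element strain is only an average and the score
    serves as a quality-control diagnostic.
    """
    if mode not in ("centroid", "gauss_mean"):
        raise ConfigurationError(f"unknown evaluation mode {mode!r}; choose centroid or gauss_mean")
    center = strain_at(pair, 0.0, 0.0, measure).as_matrix()
    gauss = []
    degenerate = False
    for xi, eta in GAUSS_POINTS:
        # on a strongly non-convex quad the bilinear map can fold at interior
        # points even when the centroid is fine; the centroid result stays
        # valid and the heterogeneity diagnostic saturates instead
        try:
            gauss.append(strain_at(pair, xi, eta, measure).as_matrix())
        except DegenerateElementError:
            degenerate = True
    if degenerate and mode == "gauss_mean":
        raise DegenerateElementError(
            "gauss_mean evaluation impossible: element is degenerate at a Gauss point"
        )
    if degenerate:
        hetero = float("inf")
    else:
        hetero = max(float(np.linalg.norm(g - center)) for g in gauss)
    chosen = center if mode == "centroid" else np.mean(gauss, axis=0)
    return StrainTensor2D.from_matrix(chosen, measure), hetero
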