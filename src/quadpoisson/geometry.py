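"""Planar marker geometry: points, four-marker quadrilaterals, deformation pairs.

A specimen's deformation is observed through four ink-spot markers on its
surface. The four global marker coordinates define a quadrilateral whose
initial and deformed shapes carry all the kinematic information the method
needs. The classes here enforce the geometric invariants downstream code
relies on: the quadrilateral is simple (non-self-intersecting), has positive
signed area, and its vertices are stored counterclockwise starting from the
lexicographically smallest vertex, so that results do not depend on the
order in which a user happens to list the markers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from shapely.geometry import Polygon

from .errors import InvalidQuadError

__all__ = ["Point2D", "MarkerQuad", "DeformationPair"]

#: Relative floor on quad area (fraction of bounding-box area) below which the
#: element is treated as degenerate.
_MIN_AREA_FRACTION = 1e-9


@dataclass(frozen=True)
class Point2D:
    """A point in global coordinates, in millimetres."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise InvalidQuadError(f"non-finite coordinates ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


def _as_vertex_array(vertices) -> np.ndarray:
    if isinstance(vertices, np.ndarray):
        v = vertices.astype(float, copy=True)
    else:
        v = np.array(
            [p.as_array() if isinstance(p, Point2D) else np.asarray(p, float) for p in vertices],
            dtype=float,
        )
    if v.shape != (4, 2):
        raise InvalidQuadError(f"expected 4 vertices of 2 coordinates, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise InvalidQuadError("non-finite vertex coordinates")
    return v


def signed_area(vertices: np.ndarray) -> float:
    """Shoelace signed area of a polygon given by its vertex cycle."""
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _is_simple(vertices: np.ndarray) -> bool:
    # shapely flags self-intersecting or zero-area rings as invalid
    return Polygon(vertices).is_valid


def _angular_order(vertices: np.ndarray) -> np.ndarray:
    c = vertices.mean(axis=0)
    ang = np.arctan2(vertices[:, 1] - c[1], vertices[:, 0] - c[0])
    return np.argsort(ang)


class MarkerQuad:
    """Four ordered markers forming a simple, positively oriented quadrilateral.

    Parameters
    ----------
    vertices : array-like of shape (4, 2), or sequence of Point2D
        Marker coordinates in mm.
    labels : sequence of 4 str, optional
        Marker identifiers; defaults to ``m1..m4`` in the given order.
    canonicalize : bool
        If True (default), the vertex cycle is normalised: the given cyclic
        order is kept when it already forms a simple polygon (otherwise an
        angular sort around the centroid is attempted), orientation is made
        counterclockwise, and the cycle is rotated to start at the
        lexicographically smallest vertex. Labels travel with their vertices.
        If False the order is taken as-is but still validated.
    """

    __slots__ = ("vertices", "labels")

    def __init__(self, vertices, labels: Sequence[str] | None = None, *, canonicalize: bool = True):
        v = _as_vertex_array(vertices)
        if labels is None:
            labels = [f"m{i + 1}" for i in range(4)]
        labels = [str(s) for s in labels]
        if len(labels) != 4 or len(set(labels)) != 4:
            raise InvalidQuadError(f"need 4 distinct marker labels, got {labels}")

        # coincident markers cannot define an element
        for i in range(4):
            for j in range(i + 1, 4):
                if np.array_equal(v[i], v[j]):
                    raise InvalidQuadError(
                        f"markers {labels[i]!r} and {labels[j]!r} coincide at {tuple(v[i])}"
                    )

        order = np.arange(4)
        if canonicalize:
            if not _is_simple(v):
                order = _angular_order(v)
                if not _is_simple(v[order]):
                    raise InvalidQuadError("markers do not form a simple quadrilateral")
            v2 = v[order]
            if signed_area(v2) < 0.0:
                order = order[::-1]
                v2 = v[order]
            # start the cycle at the lexicographically smallest vertex
            start = int(np.lexsort((v2[:, 1], v2[:, 0]))[0])
            order = np.roll(order, -start)
            v = v[order]
            labels = [labels[i] for i in order]
        else:
            if not _is_simple(v):
                raise InvalidQuadError("markers do not form a simple quadrilateral")
            if signed_area(v) < 0.0:
                raise InvalidQuadError("vertex cycle is clockwise (orientation-reversing)")

        area = signed_area(v)
        span = v.max(axis=0) - v.min(axis=0)
        bbox = float(span[0] * span[1]) if span.min() > 0 else 0.0
        if area <= 0.0 or (bbox > 0 and area < _MIN_AREA_FRACTION * bbox) or bbox == 0.0:
            raise InvalidQuadError(f"degenerate quadrilateral (signed area {area:g})")

        v.setflags(write=False)
        self.vertices = v
        self.labels = tuple(labels)

    # -- accessors ---------------------------------------------------------

    @property
    def signed_area(self) -> float:
        return signed_area(self.vertices)

    @property
    def centroid(self) -> Point2D:
        c = self.vertices.mean(axis=0)
        return Point2D(float(c[0]), float(c[1]))

    def points(self) -> list[Point2D]:
        return [Point2D(float(x), float(y)) for x, y in self.vertices]

    def vertices_for(self, labels: Sequence[str]) -> np.ndarray:
        """Vertices reordered to match ``labels`` (a permutation of ours)."""
        index = {lab: i for i, lab in enumerate(self.labels)}
        try:
            idx = [index[str(s)] for s in labels]
        except KeyError as exc:
            raise InvalidQuadError(f"unknown marker label {exc.args[0]!r}") from exc
        return self.vertices[idx]

    def transformed(self, matrix: np.ndarray | None = None, translation=(0.0, 0.0)) -> "MarkerQuad":
        """Apply ``v -> matrix @ v + translation`` to every vertex."""
        v = self.vertices
        if matrix is not None:
            v = v @ np.asarray(matrix, float).T
        v = v + np.asarray(translation, float)
        return MarkerQuad(v, self.labels)

    def __repr__(self) -> str:  # pragma: no cover
        pts = ", ".join(f"{lab}=({x:g},{y:g})" for lab, (x, y) in zip(self.labels, self.vertices))
        return f"MarkerQuad({pts})"


class DeformationPair:
    """Initial and deformed configurations of the same four physical markers.

    The deformed quad's vertices are re-indexed by marker label to follow the
    initial quad's canonical order, so the k-th vertex of both configurations
    is the same physical marker. The displacement of each vertex between the
    two configurations is the element's kinematic input.
    """

    __slots__ = ("initial", "deformed")

    def __init__(self, initial: MarkerQuad, deformed: MarkerQuad):
        if set(initial.labels) != set(deformed.labels):
            raise InvalidQuadError(
                f"marker label mismatch: {sorted(initial.labels)} vs {sorted(deformed.labels)}"
            )
        aligned = deformed.vertices_for(initial.labels)
        self.initial = initial
        # orientation/validity re-checked in the label order imposed by `initial`
        self.deformed = MarkerQuad(aligned, initial.labels, canonicalize=False)

    @classmethod
    def from_arrays(cls, initial, deformed, labels: Sequence[str] | None = None) -> "DeformationPair":
        """Build a pair from two (4, 2) arrays with row-wise marker correspondence."""
        if labels is None:
            labels = [f"m{i + 1}" for i in range(4)]
        return cls(MarkerQuad(initial, labels), MarkerQuad(deformed, labels))

    @property
    def displacements(self) -> np.ndarray:
        """Vertex displacements, deformed minus initial, in initial label order."""
        return self.deformed.vertices - self.initial.vertices

    def transformed(self, matrix=None, translation=(0.0, 0.0), which: str = "both") -> "DeformationPair":
        """Rigidly transform one or both configurations (for invariance studies)."""
        ini, def_ = self.initial, self.deformed
        if which in ("both", "initial"):
            ini = ini.transformed(matrix, translation)
        if which in ("both", "deformed"):
            def_ = def_.transformed(matrix, translation)
        return DeformationPair(ini, def_)
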