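"""Closed planar contours and scalar Minkowski functionals.

A cell outline is represented as an ordered, implicitly closed polyline.
The three scalar Minkowski functionals of a two-dimensional body are its
area (W0), its boundary length (W1) and the integrated signed curvature of
the boundary (W2).  For a polyline the curvature is concentrated at the
vertices, so W2 is the sum of signed exterior (turning) angles, which is
2*pi for every simple counterclockwise contour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Contour",
    "area",
    "perimeter",
    "curvature_integral",
    "centroid",
    "edge_normals",
]

#: relative tolerance (fraction of the bounding-box diagonal) below which two
#: consecutive vertices are considered duplicates
DUPLICATE_RTOL = 1e-12


class DegenerateContourError(ValueError):
    """Raised for contours with fewer than 3 distinct vertices or zero area."""


def _signed_area(vertices: np.ndarray) -> float:
    """Shoelace signed area of an implicitly closed polyline."""
    x = vertices[:, 0]
    y = vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class Contour:
    """Ordered closed planar polyline bounding one cell.

    Parameters
    ----------
    vertices
        ``(n, 2)`` array-like of points in physical units (pixels for
        image-traced contours unless rescaled).  The polyline is implicitly
        closed; a duplicate closing vertex is removed on construction.
    kind
        ``"polygon"`` when the vertex list is meaningful as such (corners of
        a true polygon), ``"sampled"`` for dense samplings of smooth curves.
    box
        optional ``(width, height)`` of a periodic rectangular domain.
    cell_id, frame
        optional provenance identifiers.

    Orientation is normalized to counterclockwise (positive shoelace area)
    on construction, so outward edge normals point away from the interior.
    """

    vertices: np.ndarray
    kind: str = "polygon"
    box: Optional[Tuple[float, float]] = None
    cell_id: Optional[int] = None
    frame: Optional[int] = None

    def __init__(
        self,
        vertices: Sequence[Sequence[float]],
        kind: str = "polygon",
        box: Optional[Tuple[float, float]] = None,
        cell_id: Optional[int] = None,
        frame: Optional[int] = None,
    ):
        v = np.asarray(vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise DegenerateContourError("degenerate contour: need >= 3 2-d vertices")
        if kind not in ("polygon", "sampled"):
            raise ValueError(f"unknown contour kind {kind!r}")
        # drop explicit closing vertex and consecutive duplicates
        lo = v.min(axis=0)
        hi = v.max(axis=0)
        diag = float(np.hypot(*(hi - lo)))
        if diag == 0.0:
            raise DegenerateContourError("degenerate contour: all vertices coincide")
        tol = DUPLICATE_RTOL * diag
        keep = np.linalg.norm(v - np.roll(v, 1, axis=0), axis=1) > tol
        v = v[keep]
        if v.shape[0] < 3:
            raise DegenerateContourError("degenerate contour: < 3 distinct vertices")
        sa = _signed_area(v)
        if sa == 0.0:
            raise DegenerateContourError("degenerate contour: zero area")
        if sa < 0.0:
            v = v[::-1].copy()
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "box", box)
        object.__setattr__(self, "cell_id", cell_id)
        object.__setattr__(self, "frame", frame)
        self.vertices.setflags(write=False)

    # -- derived edge quantities ------------------------------------------

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def edge_vectors(self) -> np.ndarray:
        """``(n, 2)`` vectors from each vertex to the next (closing edge last)."""
        return np.roll(self.vertices, -1, axis=0) - self.vertices

    def edge_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.edge_vectors(), axis=1)

    def transformed(self, rotation: float = 0.0, translation=(0.0, 0.0), scale: float = 1.0) -> "Contour":
        """Rigidly transformed (and optionally uniformly scaled) copy."""
        c, s = np.cos(rotation), np.sin(rotation)
        rot = np.array([[c, -s], [s, c]])
        v = scale * self.vertices @ rot.T + np.asarray(translation, dtype=float)
        return Contour(v, kind=self.kind, box=self.box, cell_id=self.cell_id, frame=self.frame)


def area(contour: Contour) -> float:
    """W0: enclosed area (positive for the normalized CCW orientation)."""
    return _signed_area(contour.vertices)


def perimeter(contour: Contour) -> float:
    """W1: total boundary length including the closing edge."""
    return float(contour.edge_lengths().sum())


def curvature_integral(contour: Contour) -> float:
    """W2: integrated contour curvature.

    For a polyline the curvature is a sum of Dirac contributions at the
    vertices, each equal to the signed exterior angle, so the integral is the
    total turning of the tangent: 2*pi for any simple CCW contour.
    """
    e = contour.edge_vectors()
    prev = np.roll(e, 1, axis=0)
    cross = prev[:, 0] * e[:, 1] - prev[:, 1] * e[:, 0]
    dot = np.sum(prev * e, axis=1)
    return float(np.arctan2(cross, dot).sum())


def centroid(contour: Contour, mode: str = "area") -> np.ndarray:
    """Centroid of the contour.

    ``mode="area"`` gives the center of mass of the enclosed region (first
    area moment / area); ``mode="vertex_mean"`` the arithmetic mean of the
    vertex list.  The two differ for unevenly sampled vertex lists, which is
    exactly the sensitivity exploited by vertex-based shape functions.
    """
    v = contour.vertices
    if mode == "vertex_mean":
        return v.mean(axis=0)
    if mode == "area":
        x, y = v[:, 0], v[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a = 0.5 * cross.sum()
        cx = np.sum((x + xn) * cross) / (6.0 * a)
        cy = np.sum((y + yn) * cross) / (6.0 * a)
        return np.array([cx, cy])
    raise ValueError(f"unknown centroid mode {mode!r}")


def edge_normals(contour: Contour) -> tuple[np.ndarray, np.ndarray]:
    """Outward unit-normal angles per edge.

    Returns ``(lengths, angles)``: edge lengths and the angle theta_n of each
    edge's outward normal with the x-axis, in ``[0, 2*pi)``.  For a CCW
    contour the outward normal is the tangent rotated by -pi/2.
    """
    e = contour.edge_vectors()
    lengths = np.linalg.norm(e, axis=1)
    # tangent (dx, dy) -> outward normal (dy, -dx)
    angles = np.mod(np.arctan2(-e[:, 0], e[:, 1]), 2.0 * np.pi)
    return lengths, angles
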