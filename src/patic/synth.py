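"""Synthetic shapes and tissues.

Generators for every input the analysis needs without external data:
regular and corner-rounded polygons, ellipses, star-convex random blobs,
the vertex-collapse quadrilateral family that exposes the instability of
vertex-based descriptors, and Lloyd-relaxable Voronoi tissues (a
disorder-tunable stand-in for confluent monolayers).  All generators are
deterministic given their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .geometry import Contour, area, centroid

__all__ = [
    "TissueFrame",
    "regular_polygon",
    "rounded_regular_polygon",
    "ellipse",
    "collapse_family",
    "voronoi_tissue",
    "rasterize",
    "random_blob",
]


@dataclass
class TissueFrame:
    """All cell contours of one frame plus domain metadata.

    ``boundary_cells`` holds the ids of cells touching the domain boundary
    (empty for periodic tissues); such cells are excluded from statistics by
    default since their contours are truncated.  ``label_image`` is attached
    when the frame originated from (or was rasterized to) a segmentation.
    """

    frame: int
    contours: List[Contour]
    box: Optional[Tuple[float, float]] = None
    periodic: bool = False
    provenance: str = "generated"
    label_image: Optional[np.ndarray] = None
    pixel_size: float = 1.0
    boundary_cells: Set[int] = field(default_factory=set)
    seeds: Optional[np.ndarray] = None

    def __post_init__(self):
        ids = [c.cell_id for c in self.contours]
        if len(ids) != len(set(ids)):
            raise ValueError("cell ids must be unique within a frame")

    @property
    def n_cells(self) -> int:
        return len(self.contours)

    def interior_contours(self) -> List[Contour]:
        return [c for c in self.contours if c.cell_id not in self.boundary_cells]


# ---------------------------------------------------------------------------
# single shapes


def regular_polygon(m: int, circumradius: float = 1.0, rotation: float = 0.0,
                    center: Sequence[float] = (0.0, 0.0)) -> Contour:
    """Regular m-gon with vertices on a circle of the given radius."""
    if m < 3:
        raise ValueError("m must be >= 3")
    if circumradius <= 0:
        raise ValueError("circumradius must be positive")
    ang = rotation + 2.0 * np.pi * np.arange(m) / m
    v = np.column_stack([np.cos(ang), np.sin(ang)]) * circumradius + np.asarray(center, dtype=float)
    return Contour(v, kind="polygon")


def rounded_regular_polygon(m: int, circumradius: float, corner_radius: float,
                            samples_per_arc: int = 64, rotation: float = 0.0,
                            center: Sequence[float] = (0.0, 0.0)) -> Contour:
    """Regular m-gon with corners replaced by tangent circular arcs.

    Each corner arc has radius ``corner_radius`` and sweeps the polygon's
    exterior angle 2*pi/m; straight segments between tangent points are kept
    as single edges.  ``corner_radius`` equal to the inradius gives a circle;
    larger values would make the arcs overlap and raise.
    """
    if m < 3:
        raise ValueError("m must be >= 3")
    inradius = circumradius * np.cos(np.pi / m)
    if corner_radius < 0:
        raise ValueError("corner_radius must be >= 0")
    if corner_radius > inradius * (1 + 1e-12):
        raise ValueError("corner arcs overlap: corner_radius exceeds the inradius")
    if corner_radius == 0:
        return regular_polygon(m, circumradius, rotation, center)
    phi = rotation + 2.0 * np.pi * np.arange(m) / m
    # arc centers sit on the shrunk circumcircle so arcs are tangent to edges
    c_r = circumradius - corner_radius / np.cos(np.pi / m)
    pts = []
    for k in range(m):
        th = np.linspace(phi[k] - np.pi / m, phi[k] + np.pi / m, samples_per_arc)
        cx = c_r * np.cos(phi[k])
        cy = c_r * np.sin(phi[k])
        pts.append(np.column_stack([cx + corner_radius * np.cos(th),
                                    cy + corner_radius * np.sin(th)]))
    v = np.concatenate(pts) + np.asarray(center, dtype=float)
    return Contour(v, kind="sampled")


def ellipse(a: float, b: float, n: int = 256, rotation: float = 0.0,
            center: Sequence[float] = (0.0, 0.0)) -> Contour:
    """Axis-aligned ellipse with semi-axes a (x) and b (y), densely sampled."""
    if a <= 0 or b <= 0:
        raise ValueError("semi-axes must be positive")
    if n < 64:
        raise ValueError("n must be >= 64")
    t = 2.0 * np.pi * np.arange(n) / n
    v = np.column_stack([a * np.cos(t), b * np.sin(t)])
    if rotation:
        c, s = np.cos(rotation), np.sin(rotation)
        v = v @ np.array([[c, -s], [s, c]]).T
    return Contour(v + np.asarray(center, dtype=float), kind="sampled")


def collapse_family(s: float, bulge: float = 0.0) -> Contour:
    """Quadrilateral family collapsing onto an equilateral triangle.

    Vertices A=(0,0), B=(1,0), C=(0.5, sqrt(3)/2) and a fourth vertex
    D = C + s*(A - C) + bulge*n, with n the outward unit normal of edge CA.
    With ``bulge = 0`` the fourth vertex is collinear on edge CA, so the
    traced geometry is exactly the triangle for every s: contour-based
    descriptors are constant along the family while the vertex-based
    gamma_p jumps as D merges with C (s -> 0).  With ``bulge > 0`` the
    quadrilateral genuinely deforms and converges to the triangle as
    bulge -> 0.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError("s must lie in [0, 1]")
    if bulge < 0:
        raise ValueError("bulge must be >= 0")
    A = np.array([0.0, 0.0])
    B = np.array([1.0, 0.0])
    C = np.array([0.5, np.sqrt(3.0) / 2.0])
    t = (A - C) / np.linalg.norm(A - C)  # tangent of edge C -> A
    n_out = np.array([t[1], -t[0]])  # outward normal of the CCW contour
    D = C + s * (A - C) + bulge * n_out
    return Contour([A, B, C, D], kind="polygon")


def random_blob(seed: int, n_harmonics: int = 4, amplitude: float = 0.3,
                n_samples: int = 256, r0: float = 1.0) -> Contour:
    """Star-convex random shape with a seeded Fourier radius perturbation.

    r(phi) = r0 * (1 + sum_k a_k cos(k phi + phi_k)) for k = 2..n_harmonics+1,
    with sum |a_k| = amplitude < 1 so the radius stays positive.
    """
    if not 0.0 <= amplitude < 1.0:
        raise ValueError("amplitude must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    ks = np.arange(2, n_harmonics + 2)
    a = rng.random(len(ks))
    total = a.sum()
    a = a / total * amplitude if amplitude > 0 and total > 0 else np.zeros_like(a)
    ph = rng.uniform(0, 2 * np.pi, len(ks))
    phi = 2.0 * np.pi * np.arange(n_samples) / n_samples
    r = r0 * (1.0 + np.sum(a[:, None] * np.cos(ks[:, None] * phi[None, :] + ph[:, None]), axis=0))
    v = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    return Contour(v, kind="sampled")


# ---------------------------------------------------------------------------
# tissues


def _voronoi_cells_periodic(seeds: np.ndarray, box: Tuple[float, float]) -> List[np.ndarray]:
    """Voronoi cell polygon (unwrapped) of each seed in a periodic box."""
    from scipy.spatial import Voronoi

    w, h = box
    shifts = [(dx, dy) for dy in (-h, 0.0, h) for dx in (-w, 0.0, w)]
    tiled = np.concatenate([seeds + np.array(s) for s in shifts])
    vor = Voronoi(tiled)
    zero = shifts.index((0.0, 0.0))
    n = len(seeds)
    polys = []
    for i in range(zero * n, (zero + 1) * n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            raise RuntimeError("unbounded periodic Voronoi cell (too few seeds?)")
        polys.append(vor.vertices[region])
    return polys


def _voronoi_cells_bounded(seeds: np.ndarray, box: Tuple[float, float]) -> List[np.ndarray]:
    """Voronoi cells clipped exactly to the box via mirror-image seeds."""
    from scipy.spatial import Voronoi

    w, h = box
    mirrors = [
        seeds * np.array([-1, 1]),                       # left edge x=0
        seeds * np.array([-1, 1]) + np.array([2 * w, 0]),  # right edge x=w
        seeds * np.array([1, -1]),                       # bottom y=0
        seeds * np.array([1, -1]) + np.array([0, 2 * h]),  # top y=h
    ]
    allpts = np.concatenate([seeds] + mirrors)
    vor = Voronoi(allpts)
    polys = []
    for i in range(len(seeds)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            raise RuntimeError("unbounded Voronoi cell despite mirroring")
        polys.append(vor.vertices[region])
    return polys


def voronoi_tissue(n_cells: int, box: Tuple[float, float] = (10.0, 10.0),
                   lloyd_iterations: int = 0, seed: int = 0,
                   periodic: bool = True, frame: int = 0) -> TissueFrame:
    """Voronoi tessellation of seeded random points, optionally relaxed.

    Lloyd relaxation moves each seed to its cell's area centroid and
    retessellates; many iterations drive the tissue toward a hexagonal
    packing (high hexatic order), zero iterations give a disordered tissue.
    Deterministic under (seed, parameters).
    """
    if n_cells < 3:
        raise ValueError("n_cells must be >= 3")
    w, h = box
    rng = np.random.default_rng(seed)
    seeds = rng.uniform(0, 1, size=(n_cells, 2)) * np.array([w, h])

    def build(pts):
        if periodic:
            return _voronoi_cells_periodic(pts, (w, h))
        return _voronoi_cells_bounded(pts, (w, h))

    for _ in range(lloyd_iterations):
        polys = build(seeds)
        new = []
        for poly in polys:
            c = centroid(Contour(poly), "area")
            new.append(np.mod(c, [w, h]) if periodic else np.clip(c, [0, 0], [w, h]))
        seeds = np.asarray(new)

    polys = build(seeds)
    contours = []
    boundary: Set[int] = set()
    tol = 1e-9 * max(w, h)
    for i, poly in enumerate(polys):
        c = Contour(poly, kind="polygon", box=(w, h) if periodic else None,
                    cell_id=i, frame=frame)
        contours.append(c)
        if not periodic:
            v = c.vertices
            if (v[:, 0] < tol).any() or (v[:, 0] > w - tol).any() or \
               (v[:, 1] < tol).any() or (v[:, 1] > h - tol).any():
                boundary.add(i)
    return TissueFrame(frame=frame, contours=contours, box=(w, h), periodic=periodic,
                       provenance="generated", boundary_cells=boundary, seeds=seeds)


def rasterize(tissue: TissueFrame, pixels_per_unit: float = 10.0) -> np.ndarray:
    """Integer label image of a tissue (0 = background).

    Each pixel takes the label ``cell_id + 1`` of the cell containing its
    center; image rows run top-to-bottom (row 0 is the highest y), matching
    the file convention of label TIFF/PNG segmentations.  For periodic
    tissues every pixel is covered (seam pixels resolved by minimum-image
    nearest centroid); bounded tissues may leave background outside cells.
    """
    if pixels_per_unit <= 0:
        raise ValueError("pixels_per_unit must be positive")
    if tissue.box is None:
        raise ValueError("rasterize requires a frame with a box")
    import shapely
    import shapely.affinity

    w, h = tissue.box
    nx = int(round(w * pixels_per_unit))
    ny = int(round(h * pixels_per_unit))
    xs = (np.arange(nx) + 0.5) / pixels_per_unit
    ys = (np.arange(ny) + 0.5) / pixels_per_unit
    gx, gy = np.meshgrid(xs, ys)  # gy rows: increasing y (math orientation)
    labels = np.zeros((ny, nx), dtype=np.int32)

    shifts = [(0.0, 0.0)]
    if tissue.periodic:
        shifts = [(dx, dy) for dx in (-w, 0.0, w) for dy in (-h, 0.0, h)]
    for c in tissue.contours:
        poly = shapely.Polygon(c.vertices)
        for dx, dy in shifts:
            moved = shapely.affinity.translate(poly, dx, dy) if (dx or dy) else poly
            minx, miny, maxx, maxy = moved.bounds
            i0 = max(0, int(np.floor(miny * pixels_per_unit)) - 1)
            i1 = min(ny, int(np.ceil(maxy * pixels_per_unit)) + 1)
            j0 = max(0, int(np.floor(minx * pixels_per_unit)) - 1)
            j1 = min(nx, int(np.ceil(maxx * pixels_per_unit)) + 1)
            if i0 >= i1 or j0 >= j1:
                continue
            sub_x = gx[i0:i1, j0:j1]
            sub_y = gy[i0:i1, j0:j1]
            inside = shapely.contains_xy(moved, sub_x.ravel(), sub_y.ravel()).reshape(sub_x.shape)
            block = labels[i0:i1, j0:j1]
            block[inside & (block == 0)] = c.cell_id + 1
            labels[i0:i1, j0:j1] = block

    if tissue.periodic:
        # pixels exactly on shared edges: nearest centroid, minimum image
        missing = labels == 0
        if missing.any():
            cents = np.array([centroid(c, "area") for c in tissue.contours])
            ids = np.array([c.cell_id for c in tissue.contours])
            pts = np.column_stack([gx[missing], gy[missing]])
            d = pts[:, None, :] - cents[None, :, :]
            d -= np.array([w, h]) * np.round(d / np.array([w, h]))
            labels[missing] = ids[np.argmin((d**2).sum(-1), axis=1)] + 1
    return labels[::-1, :]  # flip to image convention (row 0 = top)
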