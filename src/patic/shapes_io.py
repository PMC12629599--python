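"""Readers, writers and contour extraction for segmented tissues.

Label images (integer segmentations, 0 = background) are turned into
per-cell contours by tracing the pixel-boundary "crack" polygon along
pixel edges, so the traced area equals the pixel count exactly.  An
optional circular moving average smooths the staircase (which otherwise
inflates 4-atic order).  A junction-based polygonalization places polygon
vertices where at least three regions meet, approximating cells by true
polygons for comparison with vertex-based descriptors.

File-space convention: row 0 is the top of the image, x grows rightward,
y downward; coordinates are converted to y-upward mathematical coordinates
(in physical units via ``pixel_size``) on load.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .geometry import Contour
from .synth import TissueFrame

__all__ = [
    "LabelField",
    "read_labels",
    "extract_contours",
    "polygonalize",
    "read_polygons",
    "write_polygons",
    "write_measures",
]


@dataclass
class LabelField:
    """Integer-label segmentation of one frame (0 = background)."""

    data: np.ndarray
    pixel_size: float = 1.0
    frame: int = 0

    def __post_init__(self):
        arr = np.asarray(self.data)
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("labels must be integers")
        if arr.ndim != 2:
            raise ValueError("label field must be 2-d")
        if arr.min() < 0:
            raise ValueError("labels must be non-negative")
        self.data = arr

    def validate_connectivity(self) -> "LabelField":
        """Keep only the largest 4-connected component of each label.

        Multi-component labels indicate a segmentation defect; a warning is
        issued and the smaller fragments are cleared to background.
        """
        from scipy import ndimage

        out = self.data.copy()
        for lab in np.unique(out):
            if lab == 0:
                continue
            mask = out == lab
            comps, n = ndimage.label(mask)
            if n > 1:
                warnings.warn(f"label {lab} has {n} 4-connected components; "
                              "keeping the largest", stacklevel=2)
                sizes = ndimage.sum(mask, comps, index=np.arange(1, n + 1))
                keep = 1 + int(np.argmax(sizes))
                out[mask & (comps != keep)] = 0
        return LabelField(out, pixel_size=self.pixel_size, frame=self.frame)

    def labels(self) -> np.ndarray:
        u = np.unique(self.data)
        return u[u > 0]


def read_labels(path, fmt: Optional[str] = None, pixel_size: float = 1.0) -> List[LabelField]:
    """Read a label image; multi-page TIFFs give one field per page."""
    path = Path(path)
    if fmt is None:
        fmt = "tiff" if path.suffix.lower() in (".tif", ".tiff") else "png"
    if fmt == "tiff":
        import tifffile

        pages = tifffile.imread(path)
        if pages.ndim == 2:
            pages = pages[None]
    elif fmt == "png":
        import imageio.v3 as iio

        img = iio.imread(path)
        if img.ndim != 2:
            raise ValueError("labels must be single-channel (got RGB/RGBA PNG)")
        pages = img[None]
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if not np.issubdtype(pages.dtype, np.integer):
        raise ValueError("labels must be integers")
    return [LabelField(pages[k], pixel_size=pixel_size, frame=k) for k in range(len(pages))]


# ---------------------------------------------------------------------------
# crack-boundary tracing

_LEFT_TURN = {(1, 0): (0, 1), (0, 1): (-1, 0), (-1, 0): (0, -1), (0, -1): (1, 0)}


def _trace_crack_cycles(mask_math: np.ndarray) -> List[np.ndarray]:
    """Directed boundary cycles of a binary mask, interior on the left.

    ``mask_math`` is indexed [iy, ix] with iy increasing upward; pixel
    (iy, ix) covers [ix, ix+1] x [iy, iy+1] on the corner lattice.  Returns
    CCW outer cycles (and CW hole cycles) as integer vertex arrays.
    """
    ny, nx = mask_math.shape
    padded = np.zeros((ny + 2, nx + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask_math
    edges: Dict[Tuple[int, int], List[Tuple[int, int]]] = {}

    filled = np.argwhere(mask_math)
    for iy, ix in filled:
        py, px = iy + 1, ix + 1
        if not padded[py - 1, px]:  # below empty: bottom edge, +x
            edges.setdefault((ix, iy), []).append((ix + 1, iy))
        if not padded[py, px + 1]:  # right edge, +y
            edges.setdefault((ix + 1, iy), []).append((ix + 1, iy + 1))
        if not padded[py + 1, px]:  # top edge, -x
            edges.setdefault((ix + 1, iy + 1), []).append((ix, iy + 1))
        if not padded[py, px - 1]:  # left edge, -y
            edges.setdefault((ix, iy + 1), []).append((ix, iy))

    cycles = []
    while edges:
        start = next(iter(edges))
        cycle = [start]
        cur = start
        prev_dir = None
        while True:
            outs = edges[cur]
            if len(outs) == 1 or prev_dir is None:
                nxt = outs.pop(0)
            else:
                # checkerboard corner: prefer the left turn to stay on the
                # 4-connected component whose interior is on our left
                want = _LEFT_TURN[prev_dir]
                pick = 0
                for k, cand in enumerate(outs):
                    d = (cand[0] - cur[0], cand[1] - cur[1])
                    if d == want:
                        pick = k
                        break
                nxt = outs.pop(pick)
            if not outs:
                del edges[cur]
            prev_dir = (nxt[0] - cur[0], nxt[1] - cur[1])
            if nxt == start:
                break
            cycle.append(nxt)
            cur = nxt
        cycles.append(np.asarray(cycle, dtype=float))
    return cycles


def _outer_cycle(cycles: List[np.ndarray]) -> np.ndarray:
    def signed_area(v):
        x, y = v[:, 0], v[:, 1]
        return 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)

    return max(cycles, key=signed_area)


def _merge_collinear(v: np.ndarray) -> np.ndarray:
    d = np.roll(v, -1, axis=0) - v
    prev = np.roll(d, 1, axis=0)
    turn = prev[:, 0] * d[:, 1] - prev[:, 1] * d[:, 0]
    keep = turn != 0
    return v[keep] if keep.sum() >= 3 else v


def _smooth_closed(v: np.ndarray, window: int) -> np.ndarray:
    if window % 2 == 0 or window < 3:
        raise ValueError("smoothing_window must be odd and >= 3 (or 0 for off)")
    k = window // 2
    idx = np.arange(-k, k + 1)
    n = len(v)
    out = np.zeros_like(v)
    for off in idx:
        out += np.roll(v, -off, axis=0)
    return out / window


def extract_contours(labels: LabelField, smoothing_window: int = 0,
                     exclude_boundary: bool = True) -> TissueFrame:
    """Per-cell contours traced along pixel edges.

    The traced polygon of each label follows the cracks between its pixels
    and the exterior, so its area equals the pixel count exactly (in pixel
    units; scaled by ``pixel_size``).  ``smoothing_window`` (odd, in crack
    vertices of unit step) applies a circular moving average, yielding
    ``kind="sampled"`` contours; 0 keeps the exact staircase polygon with
    collinear runs merged.  Cells touching the image border are flagged
    (and, with ``exclude_boundary``, dropped).
    """
    arr = labels.data
    ids = labels.labels()
    if ids.size == 0:
        raise ValueError("label field contains no cells")
    ny = arr.shape[0]
    scale = labels.pixel_size
    math_img = arr[::-1, :]  # row 0 = bottom in math orientation

    contours = []
    boundary: set = set()
    for lab in ids:
        mask = math_img == lab
        on_border = (mask[0].any() or mask[-1].any()
                     or mask[:, 0].any() or mask[:, -1].any())
        if on_border:
            boundary.add(int(lab))
            if exclude_boundary:
                continue
        cycles = _trace_crack_cycles(mask)
        v = _outer_cycle(cycles)
        if smoothing_window:
            v = _smooth_closed(v, smoothing_window)
            kind = "sampled"
        else:
            v = _merge_collinear(v)
            kind = "polygon"
        contours.append(Contour(v * scale, kind=kind, cell_id=int(lab),
                                frame=labels.frame))
    if not contours:
        raise ValueError("no cells left after boundary exclusion")
    h_units = arr.shape[0] * scale
    w_units = arr.shape[1] * scale
    return TissueFrame(frame=labels.frame, contours=contours, box=(w_units, h_units),
                       periodic=False, provenance="label_image",
                       label_image=arr, pixel_size=scale,
                       boundary_cells=(boundary if not exclude_boundary else set()))


def polygonalize(labels: LabelField, exclude_boundary: bool = True) -> TissueFrame:
    """Polygon approximation of each cell with vertices at region junctions.

    A corner of the pixel lattice is a junction when at least three distinct
    regions (cells or background, with out-of-image counting as background)
    meet there.  Each cell's polygon is the cyclic sequence of the junctions
    encountered along its traced boundary; cells with fewer than three
    junctions fall back to their full traced contour with a warning.
    """
    arr = labels.data
    ids = labels.labels()
    if ids.size == 0:
        raise ValueError("label field contains no cells")
    scale = labels.pixel_size
    math_img = arr[::-1, :]
    ny, nx = math_img.shape

    # corner (ix, iy) touches pixels (iy-1..iy, ix-1..ix)
    pad = np.zeros((ny + 2, nx + 2), dtype=math_img.dtype)
    pad[1:-1, 1:-1] = math_img
    q = np.stack([pad[:-1, :-1], pad[:-1, 1:], pad[1:, :-1], pad[1:, 1:]])  # (4, ny+1, nx+1)
    sq = np.sort(q, axis=0)
    ndistinct = 1 + (np.diff(sq, axis=0) != 0).sum(axis=0)
    junction = ndistinct >= 3  # indexed [iy, ix]

    contours = []
    boundary: set = set()
    for lab in ids:
        mask = math_img == lab
        on_border = (mask[0].any() or mask[-1].any()
                     or mask[:, 0].any() or mask[:, -1].any())
        if on_border:
            boundary.add(int(lab))
            if exclude_boundary:
                continue
        v = _outer_cycle(_trace_crack_cycles(mask))
        isj = junction[v[:, 1].astype(int), v[:, 0].astype(int)]
        if isj.sum() < 3:
            warnings.warn(f"label {lab}: fewer than 3 junctions; keeping the "
                          "traced contour", stacklevel=2)
            contours.append(Contour(_merge_collinear(v) * scale, kind="polygon",
                                    cell_id=int(lab), frame=labels.frame))
        else:
            contours.append(Contour(v[isj] * scale, kind="polygon",
                                    cell_id=int(lab), frame=labels.frame))
    if not contours:
        raise ValueError("no cells left after boundary exclusion")
    return TissueFrame(frame=labels.frame, contours=contours,
                       box=(arr.shape[1] * scale, arr.shape[0] * scale),
                       periodic=False, provenance="label_image", label_image=arr,
                       pixel_size=scale,
                       boundary_cells=(boundary if not exclude_boundary else set()))


# ---------------------------------------------------------------------------
# polygon files


def read_polygons(path) -> List[TissueFrame]:
    """Read polygon frames from JSON or long-format CSV.

    JSON schema::

        {"frames": [{"frame": int, "box": [w, h] | null, "periodic": bool,
                     "cells": [{"id": int, "vertices": [[x, y], ...]}]}]}

    CSV columns: frame, cell_id, vertex_index, x, y.  Polygons are
    CCW-normalized on load; fewer than 3 vertices or duplicate cell ids
    raise with context.
    """
    path = Path(path)
    frames: List[TissueFrame] = []
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        for fr in payload["frames"]:
            fid = int(fr["frame"])
            box = tuple(fr["box"]) if fr.get("box") else None
            seen = set()
            contours = []
            for cell in fr["cells"]:
                cid = int(cell["id"])
                if cid in seen:
                    raise ValueError(f"frame {fid}: duplicate cell id {cid}")
                seen.add(cid)
                verts = cell["vertices"]
                if len(verts) < 3:
                    raise ValueError(f"frame {fid} cell {cid}: open polygon "
                                     f"({len(verts)} vertices)")
                contours.append(Contour(verts, kind="polygon", cell_id=cid,
                                        frame=fid, box=box))
            frames.append(TissueFrame(frame=fid, contours=contours, box=box,
                                      periodic=bool(fr.get("periodic", False)),
                                      provenance="polygon_file"))
    else:
        import pandas as pd

        df = pd.read_csv(path)
        required = {"frame", "cell_id", "vertex_index", "x", "y"}
        if not required.issubset(df.columns):
            raise ValueError(f"polygon CSV must have columns {sorted(required)}")
        for fid, fgroup in df.groupby("frame", sort=True):
            contours = []
            for cid, group in fgroup.groupby("cell_id", sort=True):
                group = group.sort_values("vertex_index")
                if len(group) < 3:
                    raise ValueError(f"frame {fid} cell {cid}: open polygon")
                contours.append(Contour(group[["x", "y"]].to_numpy(),
                                        kind="polygon", cell_id=int(cid),
                                        frame=int(fid)))
            frames.append(TissueFrame(frame=int(fid), contours=contours,
                                      provenance="polygon_file"))
    return frames


def write_polygons(frames: List[TissueFrame], path) -> None:
    """Write frames to the polygon JSON schema of :func:`read_polygons`."""
    payload = {"frames": [
        {
            "frame": f.frame,
            "box": list(f.box) if f.box else None,
            "periodic": f.periodic,
            "cells": [{"id": c.cell_id, "vertices": c.vertices.tolist()}
                      for c in f.contours],
        }
        for f in frames
    ]}
    Path(path).write_text(json.dumps(payload))


def write_measures(records, path, p_list=(2, 3, 4, 5, 6)) -> None:
    """Per-cell measures as CSV with full-precision floats.

    One row per (frame, cell_id) in deterministic order; angle columns in
    radians; floats serialized with 17 significant digits so a read-back
    reproduces the values exactly.
    """
    from .minkowski import records_to_dataframe

    df = records_to_dataframe(records, p_list=p_list)
    df.to_csv(path, index=False, float_format="%.17g")
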