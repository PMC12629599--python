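"""Minimal plotting: director overlays and radius-scan curves."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_directors", "plot_radius_scan"]


def plot_directors(frame, records, p: int = 2, ax=None, length: float = 0.6):
    """Cell outlines with p-legged director glyphs at the area centroids.

    Each cell's director theta_p is drawn as p line segments rotated by
    multiples of 2*pi/p, scaled by q_p.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for c in frame.contours:
        v = np.vstack([c.vertices, c.vertices[:1]])
        ax.plot(v[:, 0], v[:, 1], lw=0.5, color="0.6")
    for r in records:
        theta = r.thetap.get(p, np.nan)
        if not np.isfinite(theta):
            continue
        q = r.qp[p]
        x0, y0 = r.centroid_area
        leg = length * r.cell_radius * q
        for k in range(p):
            a = theta + 2 * np.pi * k / p
            ax.plot([x0, x0 + leg * np.cos(a)], [y0, y0 + leg * np.sin(a)],
                    color="C3", lw=1.2)
    ax.set_aspect("equal")
    ax.set_title(f"p={p} directors (leg length ~ q_{p})")
    return ax


def plot_radius_scan(scan, ax=None):
    """Log-log curves of the time-mean coarse-grained magnitudes vs R/R_cell."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sym = scan.kind
    for p in scan.p_list:
        ax.errorbar(scan.radii_over_rcell, scan.mean[p], yerr=scan.sem[p],
                    marker="o", label=f"$|{sym}_{p}|$")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("$R / R_{cell}$")
    ax.set_ylabel(f"time-mean $|{sym}_p|$")
    ax.legend()
    return ax
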