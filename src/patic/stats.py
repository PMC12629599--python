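"""Independence and distribution statistics for shape-order analyses.

Whether the strengths of two p-atic orders (say nematic q_2 and hexatic
q_6) measured per cell are statistically independent is assessed with the
sample distance correlation: pairwise-distance matrices of each sample are
double-centered and correlated, giving a dependence measure in [0, 1] that
vanishes (in the population) exactly under independence and captures
non-linear dependence that Pearson correlation misses.  Significance comes
from a seeded permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "IndependenceReport",
    "distance_correlation",
    "dcor_permutation_test",
    "summarize",
    "kde_pdf",
]


@dataclass(frozen=True)
class IndependenceReport:
    """Result of a distance-correlation permutation test."""

    dcor: float
    p_value: float
    n: int
    n_permutations: int
    seed: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "dcor": self.dcor,
            "p_value": self.p_value,
            "n": self.n,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "degenerate": self.degenerate,
        }


def _centered_distances(x: np.ndarray) -> np.ndarray:
    d = np.abs(x[:, None] - x[None, :])
    return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()


def distance_correlation(x, y, return_degenerate: bool = False):
    """Sample distance correlation of two univariate samples.

    Classical (biased, V-statistic) estimator: dCov^2 = mean(A * B) with A,
    B the double-centered distance matrices; dCor = dCov / sqrt(dVar_x *
    dVar_y), in [0, 1].  Equals 1 for strictly linear dependence.  Returns
    0 when either sample is constant (degenerate); with
    ``return_degenerate=True`` a (value, degenerate) pair is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d samples")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    A = _centered_distances(x)
    B = _centered_distances(y)
    dvar_x = (A * A).mean()
    dvar_y = (B * B).mean()
    if dvar_x <= 0.0 or dvar_y <= 0.0:
        return (0.0, True) if return_degenerate else 0.0
    dcov2 = (A * B).mean()
    val = float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar_x * dvar_y)))
    return (val, False) if return_degenerate else val


def dcor_permutation_test(x, y, n_permutations: int = 999, seed: int = 0) -> IndependenceReport:
    """Permutation test of independence based on distance correlation.

    y is shuffled ``n_permutations`` times with a seeded generator; the
    p-value uses the add-one convention
    p = (1 + #{dCor_perm >= dCor_obs}) / (1 + n_permutations), so it lies
    in (0, 1].  Degenerate (constant) samples report p = 1.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    obs, degenerate = distance_correlation(x, y, return_degenerate=True)
    if degenerate:
        return IndependenceReport(dcor=obs, p_value=1.0, n=x.size,
                                  n_permutations=n_permutations, seed=seed,
                                  degenerate=True)
    rng = np.random.default_rng(seed)
    # precompute the centered matrix of x once; only y is permuted
    A = _centered_distances(x)
    dvar_x = (A * A).mean()
    count = 0
    for _ in range(n_permutations):
        yp = rng.permutation(y)
        Bp = _centered_distances(yp)
        dvar_yp = (Bp * Bp).mean()
        if dvar_yp <= 0:
            continue
        stat = np.sqrt(max((A * Bp).mean(), 0.0) / np.sqrt(dvar_x * dvar_yp))
        if stat >= obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return IndependenceReport(dcor=obs, p_value=float(p), n=x.size,
                              n_permutations=n_permutations, seed=seed)


def summarize(records, p_list: Iterable[int] = (2, 3, 4, 5, 6)):
    """Pooled mean and standard deviation of q_p over all cells and frames.

    Population (divide-by-n) standard deviation: the records are treated as
    a census of the analyzed cells, not a sample from a larger one.
    Sentinel (NaN) director angles do not remove a cell: magnitudes are
    always defined.
    """
    import pandas as pd

    records = list(records)
    if not records:
        raise ValueError("no records to summarize")
    rows = []
    for p in p_list:
        vals = np.array([r.qp[p] for r in records if p in r.qp])
        if vals.size == 0:
            continue
        rows.append({"p": p, "mean_qp": float(vals.mean()),
                     "std_qp": float(vals.std()), "n": int(vals.size)})
    return pd.DataFrame(rows)


def kde_pdf(values, grid) -> np.ndarray:
    """Gaussian kernel density estimate (Scott's bandwidth) on a grid.

    Returns a 2-column array ``(value, density)``.  The density integrates
    to ~1 when the grid spans the data plus a few bandwidths.
    """
    from scipy.stats import gaussian_kde

    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(values) == 0:
        raise ValueError("constant sample has no density estimate")
    kde = gaussian_kde(values, bw_method="scott")
    return np.column_stack([grid, kde(grid)])
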