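import numpy as np
import pytest

from patic.coarse_grain import (
    COINCIDENT,
    RadiusScan,
    coarse_field,
    coarse_field_gamma,
    crossover_detect,
    frame_mean,
    mean_cell_radius,
    radius_scan,
)
from patic.minkowski import measure_contour, measure_frame
from patic.synth import TissueFrame, regular_polygon, voronoi_tissue


def cell_at(center, q=0.5, theta=0.3, p=6, radius=0.4):
    """A cell record with a prescribed shape function, placed at `center`."""
    rec = measure_contour(regular_polygon(p, radius, rotation=0.0, center=center))
    rec.qp = {p: q}
    rec.thetap = {p: theta}
    rec.centroid_area = np.asarray(center, dtype=float)
    return rec


class TestMeanCellRadius:
    def test_unit_area_cell(self):
        from patic.geometry import area

        c = regular_polygon(64, 1.0)
        c = c.transformed(scale=1.0 / np.sqrt(area(c)))  # unit area
        f = TissueFrame(frame=0, contours=[c])
        assert mean_cell_radius(f) == pytest.approx(1 / np.sqrt(np.pi), rel=1e-12)

    def test_mean_over_cells(self):
        from patic.geometry import area

        cells = []
        for target, cid in [(np.pi, 0), (4 * np.pi, 1)]:
            c = regular_polygon(256, 1.0, center=(3 * cid, 0))
            s = np.sqrt(target / area(c))
            cells.append(c.transformed(scale=s))
        for k, c in enumerate(cells):
            object.__setattr__(c, "cell_id", k)
        f = TissueFrame(frame=0, contours=cells)
        # areas pi and 4 pi give radii 1 and 2
        assert mean_cell_radius(f) == pytest.approx(1.5, rel=1e-6)

    def test_voronoi_tissue_close_to_sqrt_mean_area(self):
        # Jensen gap check: mean of sqrt(A/pi) stays within 10% of
        # sqrt(mean A / pi) = sqrt(1/pi) for 100 cells tiling a 10x10 box
        f = voronoi_tissue(100, box=(10, 10), seed=5, periodic=True)
        assert mean_cell_radius(f) == pytest.approx(np.sqrt(1.0 / np.pi), rel=0.10)

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError):
            mean_cell_radius(TissueFrame(frame=0, contours=[]))


class TestCoarseField:
    def test_single_cell_inside_circle(self):
        rec = cell_at((0.35, 0.0), q=0.7, theta=0.2)
        fld = coarse_field([rec], p=6, R=0.7, grid_spacing=1.0, box=(1.0, 1.0))
        # grid point (0,0) is at distance 0.35 < R
        assert fld.values[0, 0] == pytest.approx(0.7 * np.exp(6j * 0.2), abs=1e-12)
        assert fld.counts[0, 0] == 1

    def test_centroid_exactly_at_radius_excluded(self):
        # Theta(0) = 0: strict inequality at the circle boundary
        rec = cell_at((0.5, 0.0))
        fld = coarse_field([rec], p=6, R=0.5, grid_spacing=1.0, box=(1.0, 1.0))
        assert fld.counts[0, 0] == 0
        assert np.isnan(fld.values[0, 0].real)

    def test_opposite_directors_cancel(self):
        a = cell_at((0.2, 0.0), q=0.6, theta=0.1, p=6)
        b = cell_at((0.0, 0.2), q=0.6, theta=0.1 + np.pi / 6, p=6)
        fld = coarse_field([a, b], p=6, R=1.0, grid_spacing=1.0, box=(1.0, 1.0))
        assert abs(fld.values[0, 0]) < 1e-14

    def test_boundary_flagged_cells_excluded(self):
        rec = cell_at((0.2, 0.0))
        rec.boundary_flag = True
        with pytest.raises(ValueError):
            coarse_field([rec], p=6, R=1.0, grid_spacing=1.0, box=(1.0, 1.0))

    def test_matches_brute_force_double_loop(self):
        """Production implementation vs the literal double loop over cells
        and grid points, exact equality on a 100-cell frame."""
        f = voronoi_tissue(100, box=(10, 10), seed=11, periodic=True)
        recs = measure_frame(f, p_list=(6,))
        R = 2.3
        spacing = 0.5
        fld = coarse_field(recs, p=6, R=R, grid_spacing=spacing, box=f.box, periodic=True)
        vals = np.array([r.qp[6] * np.exp(6j * r.thetap[6]) for r in recs])
        cents = np.array([r.centroid_area for r in recs])
        ny, nx = fld.values.shape
        for iy in range(ny):
            for jx in range(nx):
                x = np.array([spacing * jx, spacing * iy])
                members = []
                for v, c in zip(vals, cents):
                    d = x - c
                    d -= 10.0 * np.round(d / 10.0)
                    if np.sqrt(d @ d) < R:
                        members.append(v)
                if not members:
                    assert np.isnan(fld.values[iy, jx].real)
                else:
                    assert fld.values[iy, jx] == np.asarray(members).sum() / len(members)
                    assert fld.counts[iy, jx] == len(members)

    def test_large_radius_reproduces_global_mean(self):
        f = voronoi_tissue(40, box=(8, 8), seed=3, periodic=True)
        recs = measure_frame(f, p_list=(2,))
        fld = coarse_field(recs, p=2, R=100.0, grid_spacing=2.0, box=f.box, periodic=True)
        g = np.mean([r.qp[2] * np.exp(2j * r.thetap[2]) for r in recs])
        assert np.allclose(fld.values, g, atol=1e-12)
        assert frame_mean(fld) == pytest.approx(g, abs=1e-12)

    def test_rotation_equivariance_of_global_mean(self):
        f = voronoi_tissue(30, box=(8, 8), seed=9, periodic=True)
        recs = measure_frame(f, p_list=(2,))
        phi = 0.9
        rot = [c.transformed(rotation=phi) for c in f.contours]
        recs_rot = [measure_contour(c, p_list=(2,)) for c in rot]
        fld0 = coarse_field(recs, p=2, R=1e3, grid_spacing=4.0, box=f.box)
        fld1 = coarse_field(recs_rot, p=2, R=1e3, grid_spacing=4.0, box=f.box)
        z0, z1 = frame_mean(fld0), frame_mean(fld1)
        assert abs(z1 - z0 * np.exp(2j * phi)) < 1e-10
        assert abs(abs(z1) - abs(z0)) < 1e-10

    def test_periodic_translation_leaves_magnitudes_unchanged(self):
        # translating a periodic tissue by a grid-commensurate offset shifts
        # the grid onto itself: the multiset of |Q_p| values is preserved
        import copy

        f = voronoi_tissue(40, box=(8, 8), seed=21, periodic=True)
        recs = measure_frame(f, p_list=(6,))
        shifted = []
        for r in recs:
            r2 = copy.deepcopy(r)
            r2.centroid_area = np.mod(r.centroid_area + np.array([2.0, -1.0]), 8.0)
            shifted.append(r2)
        kw = dict(p=6, R=2.0, grid_spacing=1.0, box=(8.0, 8.0), periodic=True)
        m0 = np.sort(np.abs(coarse_field(recs, **kw).values).ravel())
        m1 = np.sort(np.abs(coarse_field(shifted, **kw).values).ravel())
        np.testing.assert_allclose(m1, m0, atol=1e-10)


class TestGammaField:
    def test_single_polygon_reproduces_gamma(self):
        from patic.alt_measures import gamma_p

        c = regular_polygon(5, 1.0, rotation=0.4, center=(1.0, 1.0))
        rec = measure_contour(c)
        rec.gammap = {5: gamma_p(c, 5)}
        fld = coarse_field_gamma([rec], p=5, R=3.0, grid_spacing=1.0, box=(2.0, 2.0))
        assert fld.values[1, 1] == pytest.approx(rec.gammap[5], abs=1e-12)

    def test_missing_gamma_rejected(self):
        rec = measure_contour(regular_polygon(5, 1.0))
        with pytest.raises(ValueError, match="gamma"):
            coarse_field_gamma([rec], p=5, R=1.0, grid_spacing=1.0)


class TestFrameMean:
    def test_sentinels_excluded_from_mean(self):
        a = cell_at((0.25, 0.25), q=0.8, theta=0.0)
        fld = coarse_field([a], p=6, R=0.6, grid_spacing=1.0, box=(2.0, 2.0))
        defined = ~np.isnan(fld.values.real)
        assert defined.sum() >= 1 and (~defined).sum() >= 1
        assert frame_mean(fld) == pytest.approx(0.8, abs=1e-12)


class TestRadiusScanAndCrossover:
    def _scan(self, means2, means6, radii):
        r = np.asarray(radii, dtype=float)
        return RadiusScan(p_list=(2, 6), radii=r, radii_over_rcell=r,
                          mean={2: np.asarray(means2, dtype=float),
                                6: np.asarray(means6, dtype=float)},
                          std={2: np.zeros_like(r), 6: np.zeros_like(r)},
                          sem={2: np.zeros_like(r), 6: np.zeros_like(r)},
                          n_frames=1)

    def test_single_frame_sem_is_zero(self):
        f = voronoi_tissue(30, box=(8, 8), seed=2, periodic=True)
        scan = radius_scan([f], p_list=(2, 6), R_over_Rcell_list=(1.0, 2.0))
        assert np.all(scan.sem[2] == 0) and np.all(scan.sem[6] == 0)

    def test_tiny_radius_recovers_mean_qp(self):
        # circles holding (almost surely) at most one centroid: defined grid
        # points carry single-cell values, so the scan estimates mean q_p
        f = voronoi_tissue(200, box=(10, 10), seed=4, periodic=True)
        recs = measure_frame(f, p_list=(6,))
        scan = radius_scan([f], p_list=(6,), R_over_Rcell_list=(0.5,))
        qbar = np.mean([r.qp[6] for r in recs])
        assert scan.mean[6][0] == pytest.approx(qbar, rel=0.15)

    def test_linear_interpolated_crossing(self):
        scan = self._scan([0.5, 0.4], [0.3, 0.45], [1.0, 2.0])
        (x,) = crossover_detect(scan)
        # difference 0.2 -> -0.05 crosses zero at R = 1 + 0.2/0.25
        assert x == pytest.approx(1.8, abs=1e-12)

    def test_parallel_curves_have_no_crossing(self):
        scan = self._scan([0.5, 0.4], [0.3, 0.2], [1.0, 2.0])
        assert crossover_detect(scan) == []

    def test_identical_curves_reported_coincident(self):
        scan = self._scan([0.4, 0.3], [0.4, 0.3], [1.0, 2.0])
        assert crossover_detect(scan) == COINCIDENT

    def test_radius_beyond_half_width_warns(self):
        f = voronoi_tissue(30, box=(6, 6), seed=2, periodic=True)
        with pytest.warns(UserWarning, match="half the domain"):
            radius_scan([f], p_list=(2,), R_over_Rcell_list=(20.0,))
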