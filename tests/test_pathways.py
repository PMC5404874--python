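"""Trajectory construction: synthetic bundles, spline smoothing,
collateral arcs, compartment placement, population sampling."""

import numpy as np
import pytest

from pamsim.field import ElectrodeSpec, build_analytic_field, sample_potentials
from pamsim.pathways import (NODE, AnatomyContext, AxonTrajectory, BundleSpec,
                             FiberGeometry, Streamline, build_collateral,
                             compartmentalize, fit_smoothing_spline,
                             generate_streamlines, load_streamlines,
                             node_arc_positions, sample_population,
                             save_streamlines)


@pytest.fixture(scope="module")
def stn_anatomy(electrode):
    vox = []
    for x in np.arange(-4, 6.01, 1.0):
        for y in np.arange(-4, 6.01, 1.0):
            for z in np.arange(-4, 4.01, 1.0):
                if (((x - 2.5) / 2.5) ** 2 + ((y - 1.5) / 2.0) ** 2
                        + (z / 3.0) ** 2) <= 1.0:
                    vox.append([x, y, z])
    return AnatomyContext(stn_mask_mm=np.array(vox), voxel_size_mm=1.0,
                          electrode=electrode)


class TestGenerateStreamlines:
    def test_seed_determinism(self):
        a = generate_streamlines(4, jitter_sd_mm=0.3, seed=7)
        b = generate_streamlines(4, jitter_sd_mm=0.3, seed=7)
        c = generate_streamlines(4, jitter_sd_mm=0.3, seed=8)
        assert all(np.array_equal(x.points, y.points) for x, y in zip(a, b))
        assert not np.array_equal(a[0].points, c[0].points)

    def test_zero_jitter_on_offset_centerline(self):
        spec = BundleSpec()
        sls = generate_streamlines(3, spec, jitter_sd_mm=0.0, seed=0)
        t = np.linspace(0, 1, spec.n_points)
        center = spec.centerline(t)
        for s in sls:
            offsets = s.points - center
            # constant offset: all rows equal the first
            assert np.allclose(offsets, offsets[0], atol=1e-12)

    def test_degenerate_bundle_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            BundleSpec(cortical_cap_mm=(1, 2, 3), brainstem_cap_mm=(1, 2, 3))

    def test_n_must_be_positive(self):
        with pytest.raises(ValueError):
            generate_streamlines(0)


class TestSmoothingSpline:
    def test_collinear_points_stay_on_line(self):
        z = np.linspace(0, 10, 30)
        s = Streamline(np.column_stack([2 * z, -z, z]))
        out = fit_smoothing_spline(s, smoothing=4.0, resample_step_mm=0.5)
        # points remain on the parametric line x=2z, y=-z
        assert np.abs(out.points[:, 0] - 2 * out.points[:, 2]).max() < 1e-6
        assert np.abs(out.points[:, 1] + out.points[:, 2]).max() < 1e-6

    def test_zero_smoothing_interpolates(self):
        s = generate_streamlines(1, jitter_sd_mm=0.2, seed=3)[0]
        out = fit_smoothing_spline(s, smoothing=0.0, resample_step_mm=0.05)
        for p in s.points[::7]:
            assert np.linalg.norm(out.points - p, axis=1).min() < 0.05

    def test_endpoints_preserved_within_jitter(self):
        jitter = 0.3
        s = generate_streamlines(1, jitter_sd_mm=jitter, seed=5)[0]
        out = fit_smoothing_spline(s, 4.0, 0.25)
        assert np.linalg.norm(out.points[0] - s.points[0]) < jitter
        assert np.linalg.norm(out.points[-1] - s.points[-1]) < jitter

    def test_interior_idempotence(self):
        # re-splining an already-smoothed streamline must leave the curve
        # geometrically in place (points may slide along it as the arc
        # parameterization tightens, so measure distance to the curve)
        jitter = 0.3
        s = generate_streamlines(1, jitter_sd_mm=jitter, seed=1)[0]
        once = fit_smoothing_spline(s, 4.0, 0.25)
        twice = fit_smoothing_spline(once, 4.0, 0.25)
        n = len(twice.points)
        interior = twice.points[16:n - 16]  # one knot span off each end
        a, b = once.points[:-1], once.points[1:]
        ab = b - a
        L2 = (ab * ab).sum(axis=1)
        move = np.empty(len(interior))
        for i, p in enumerate(interior):
            t = np.clip(((p - a) * ab).sum(axis=1) / L2, 0.0, 1.0)
            move[i] = np.linalg.norm(a + t[:, None] * ab - p, axis=1).min()
        assert move.max() < 0.01 * jitter

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_smoothing_spline(Streamline(np.zeros((3, 3)) + np.arange(3)[:, None]))

    def test_smoothing_reduces_second_difference_of_potentials(
            self, electrode, analytic_field):
        # tractography jitter injects spurious structure into the second
        # nodal differences of sampled potentials; the spline removes it
        geom = FiberGeometry.from_diameter(5.7)
        raw = generate_streamlines(6, jitter_sd_mm=0.4, seed=11)
        worse = 0
        for s in raw:
            sm = fit_smoothing_spline(s, 4.0, 0.25)
            for curve in (s, sm):
                nodes = curve.point_at(node_arc_positions(curve.total_length,
                                                          geom))
                phi = sample_potentials(analytic_field, nodes)
                d2 = np.diff(phi, 2)
                if curve is s:
                    raw_ms = np.mean(d2 ** 2)
                else:
                    smooth_ms = np.mean(d2 ** 2)
            if smooth_ms >= raw_ms:
                worse += 1
        assert worse == 0


class TestCollateral:
    def test_single_choice_is_deterministic(self, electrode):
        g57 = FiberGeometry.from_diameter(5.7)
        g18 = FiberGeometry.from_diameter(1.8)
        z = np.linspace(-3, 3, 100)
        main = Streamline(np.column_stack([np.full_like(z, 3.0),
                                           np.zeros_like(z), z]))
        # mask with a single voxel whose axial window covers exactly one
        # node of Ranvier (nodes sit at z = -2.9995 + k * 0.5)
        anat = AnatomyContext(stn_mask_mm=np.array([[5.0, 2.0, 0.55]]),
                              voxel_size_mm=0.2, electrode=electrode)
        node_s = node_arc_positions(main.total_length, g57)
        node_z = main.point_at(node_s)[:, 2]
        eligible = np.abs(node_z - 0.55) <= 0.1
        assert eligible.sum() == 1
        traj = build_collateral(main, g57, g18, anat,
                                np.random.default_rng(0))
        expect_start = main.point_at(node_s[eligible])[0]
        assert np.allclose(traj.collateral.points[0], expect_start, atol=1e-9)
        assert np.allclose(traj.collateral.points[-1], [5.0, 2.0, 0.55],
                           atol=1e-9)

    def test_arc_geometry(self, electrode, stn_anatomy):
        g57 = FiberGeometry.from_diameter(5.7)
        g18 = FiberGeometry.from_diameter(1.8)
        z = np.linspace(-6, 6, 200)
        main = Streamline(np.column_stack([np.full_like(z, 4.0),
                                           np.zeros_like(z), z]))
        rng = np.random.default_rng(2)
        traj = build_collateral(main, g57, g18, stn_anatomy, rng)
        pts = traj.collateral.points
        chord = np.linalg.norm(pts[-1] - pts[0])
        assert chord > 0
        # arc length exceeds the chord but stays below a semicircle
        assert chord < traj.collateral.total_length < np.pi / 2 * chord

    def test_collateral_clears_electrode(self, electrode, stn_anatomy):
        g57 = FiberGeometry.from_diameter(5.7)
        g18 = FiberGeometry.from_diameter(1.8)
        rng = np.random.default_rng(4)
        z = np.linspace(-6, 6, 200)
        for x in (2.0, 3.0, 4.0):
            main = Streamline(np.column_stack([np.full_like(z, x),
                                               np.zeros_like(z), z]))
            traj = build_collateral(main, g57, g18, stn_anatomy, rng)
            dist = electrode.distance_to_shaft_axis(traj.collateral.points)
            assert dist.min() >= electrode.shaft_radius_mm

    def test_blocked_voxels_force_reachable_one(self, electrode):
        # electrode sits between the branch node and every voxel except
        # one on the fiber's own side: only that voxel can terminate
        g57 = FiberGeometry.from_diameter(5.7)
        g18 = FiberGeometry.from_diameter(1.8)
        z = np.linspace(-3, 3, 100)
        main = Streamline(np.column_stack([np.full_like(z, 1.0),
                                           np.zeros_like(z), z]))
        vox = np.array([[-1.2, 0.0, 0.0],   # behind the shaft
                        [-1.0, 0.05, 0.5],  # behind the shaft
                        [1.8, 0.0, 0.0]])   # reachable, same side
        anat = AnatomyContext(stn_mask_mm=vox, voxel_size_mm=0.5,
                              electrode=electrode)
        for seed in range(8):
            traj = build_collateral(main, g57, g18, anat,
                                    np.random.default_rng(seed),
                                    arc_style="line")
            assert np.allclose(traj.collateral.points[-1], vox[2], atol=1e-9)

    def test_no_eligible_node_raises(self, electrode):
        g57 = FiberGeometry.from_diameter(5.7)
        g18 = FiberGeometry.from_diameter(1.8)
        z = np.linspace(20, 26, 100)  # fiber entirely above the mask
        main = Streamline(np.column_stack([np.full_like(z, 3.0),
                                           np.zeros_like(z), z]))
        anat = AnatomyContext(stn_mask_mm=np.array([[2.0, 1.0, 0.0]]),
                              voxel_size_mm=1.0, electrode=electrode)
        with pytest.raises(ValueError, match="no node"):
            build_collateral(main, g57, g18, anat, np.random.default_rng(0))


class TestFiberGeometry:
    @pytest.mark.parametrize("diameter", [5.7, 1.8, 8.7, 10.0])
    def test_internode_repeat_identity(self, diameter):
        g = FiberGeometry.from_diameter(diameter)
        total = (g.node_length_um + 2 * g.mysa_length_um
                 + 2 * g.flut_length_um + 6 * g.stin_length_um)
        assert total == pytest.approx(g.internode_length_um)
        assert g.stin_length_um > 0

    def test_published_row_values(self):
        g = FiberGeometry.from_diameter(5.7)
        assert g.internode_length_um == 500.0
        assert g.node_diameter_um == 1.9
        assert g.stin_diameter_um == 3.4
        assert g.lamellae == 80

    def test_inconsistent_repeat_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            FiberGeometry(5.7, 1.0, 1.9, 3.0, 1.9, 35.0, 3.4, 70.5, 3.4,
                          999.0, 80)


class TestCompartmentalize:
    def test_node_positions_closed_form(self):
        g = FiberGeometry.from_diameter(5.7)
        z = np.linspace(0, 10, 500)
        line = Streamline(np.column_stack([z, np.zeros_like(z),
                                           np.zeros_like(z)]))
        m = compartmentalize(AxonTrajectory(main=line), g)
        node_x = m.midpoints_mm[m.main_node_indices][:, 0]
        dx = g.internode_length_um * 1e-3
        expect = 0.5 * g.node_length_um * 1e-3 + dx * np.arange(len(node_x))
        assert np.abs(node_x - expect).max() < 1e-3

    def test_node_spacing_invariant(self):
        g = FiberGeometry.from_diameter(5.7)
        s = generate_streamlines(1, jitter_sd_mm=0.0, seed=0)[0]
        m = compartmentalize(AxonTrajectory(main=s), g)
        # arc-length spacing between consecutive nodes (chord on a gently
        # curved path) equals the internodal length within 0.5%
        pos = m.midpoints_mm[m.main_node_indices]
        spacing = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        dx = g.internode_length_um * 1e-3
        assert np.abs(spacing - dx).max() < 0.005 * dx

    def test_truncation_deficit_below_one_internode(self):
        g = FiberGeometry.from_diameter(5.7)
        z = np.linspace(0, 10.3, 500)
        line = Streamline(np.column_stack([z, np.zeros_like(z),
                                           np.zeros_like(z)]))
        m = compartmentalize(AxonTrajectory(main=line), g)
        assert m.comp_type[m.n_main - 1] == NODE
        total = m.length_um[m.is_main].sum() * 1e-3
        assert total <= line.total_length
        assert line.total_length - total < g.internode_length_um * 1e-3

    def test_collateral_rules(self, electrode, stn_anatomy):
        g57 = FiberGeometry.from_diameter(5.7)
        g18 = FiberGeometry.from_diameter(1.8)
        z = np.linspace(-6, 6, 300)
        main = Streamline(np.column_stack([np.full_like(z, 3.0),
                                           np.zeros_like(z), z]))
        traj = build_collateral(main, g57, g18, stn_anatomy,
                                np.random.default_rng(1))
        m = compartmentalize(traj, g57, g18)
        coll = ~m.is_main
        assert m.length_um[coll][0] == pytest.approx(0.5)  # shortened root
        assert m.comp_type[np.nonzero(coll)[0][-1]] == NODE
        assert not m.active[np.nonzero(coll)[0][-1]]       # passive terminal
        assert m.comp_type[m.branch_parent] == NODE

    def test_too_short_trajectory_rejected(self):
        g = FiberGeometry.from_diameter(5.7)
        z = np.linspace(0, 0.4, 10)
        line = Streamline(np.column_stack([z, np.zeros_like(z),
                                           np.zeros_like(z)]))
        with pytest.raises(ValueError, match="shorter"):
            compartmentalize(AxonTrajectory(main=line), g)

    def test_midpoints_lie_on_source_curve(self):
        g = FiberGeometry.from_diameter(5.7)
        s = generate_streamlines(1, jitter_sd_mm=0.0, seed=2)[0]
        m = compartmentalize(AxonTrajectory(main=s), g)
        for p in m.midpoints_mm[::37]:
            seg = s.points
            d = np.min(np.linalg.norm(seg - p, axis=1))
            assert d < 0.5  # within one polyline step of the curve


class TestSamplePopulation:
    def test_split_counts_and_disjointness(self):
        sls = generate_streamlines(40, jitter_sd_mm=0.1, seed=0)
        a, b = sample_population(sls, 20, (12, 8), np.random.default_rng(0))
        assert len(a) == 12 and len(b) == 8
        ids_a = {id(s) for s in a}
        ids_b = {id(s) for s in b}
        assert not ids_a & ids_b
        assert len(ids_a | ids_b) == 20

    def test_full_draw_is_permutation(self):
        sls = generate_streamlines(10, jitter_sd_mm=0.1, seed=1)
        a, b = sample_population(sls, 10, (5, 5), np.random.default_rng(1))
        assert {id(s) for s in a + b} == {id(s) for s in sls}

    def test_insufficient_streamlines(self):
        sls = generate_streamlines(3, seed=0)
        with pytest.raises(ValueError):
            sample_population(sls, 5, (3, 2), np.random.default_rng(0))

    def test_bad_split(self):
        sls = generate_streamlines(5, seed=0)
        with pytest.raises(ValueError):
            sample_population(sls, 4, (1, 2), np.random.default_rng(0))


def test_streamline_file_round_trip(tmp_path):
    sls = generate_streamlines(3, jitter_sd_mm=0.2, seed=9)
    path = tmp_path / "sl.txt"
    save_streamlines(sls, path)
    back = load_streamlines(path)
    assert len(back) == 3
    for a, b in zip(sls, back):
        assert np.allclose(a.points, b.points)
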