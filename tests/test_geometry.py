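"""Synthetic capsule geometry, clock bookkeeping, and fixture meshes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capsfem.geometry import (
    ClockSector,
    GeometryParams,
    build_anatomical_frame,
    clock_hours,
    generate_capsule,
    make_fixture,
    retroversion_angle,
    rotate_about_axis,
    sector_nodes,
)
from capsfem.materials import LABRUM


class TestRetroversion:
    def test_printed_regression_at_bd_12_1(self):
        # -2.33 * 12.1 - 0.1 = -28.293 (posterior direction)
        assert retroversion_angle(12.1) == pytest.approx(-28.293)

    def test_small_bd_limit(self):
        assert retroversion_angle(1e-9) == pytest.approx(-0.1)

    def test_bd_10(self):
        assert retroversion_angle(10.0) == pytest.approx(-23.4)

    def test_rejects_nonpositive_distance(self):
        with pytest.raises(ValueError):
            retroversion_angle(0.0)
        with pytest.raises(ValueError):
            retroversion_angle(-3.0)


class TestAnatomicalFrame:
    def test_explicit_rotation_of_retroversion_axis(self):
        # junction line +y, humeral axis +z: retroversion axis is +x, and a
        # -30 deg retroversion puts the trans-epicondylar axis 30 deg below +x
        bd = (30.0 - 0.1) / 2.33  # BD giving exactly -30 degrees
        frame = build_anatomical_frame(
            sphere_center=(0, 0, 0),
            sphere_radius=24.0,
            humeral_axis=(0, 0, 1),
            junction_line=(0, 1, 0),
            bicipital_distance=bd,
        )
        np.testing.assert_allclose(frame.retroversion_axis, [1, 0, 0], atol=1e-12)
        expected = [np.cos(np.radians(-30)), np.sin(np.radians(-30)), 0.0]
        np.testing.assert_allclose(frame.transepicondylar_axis, expected, atol=1e-9)

    def test_zero_retroversion_alignment(self):
        bd = 0.1 / 2.33  # regression gives ~ -0.2 deg; use tiny angle instead
        frame = build_anatomical_frame((0, 0, 0), 20.0, (0, 0, 1), (1, 0, 0), bd)
        angle = np.degrees(
            np.arccos(
                np.clip(frame.retroversion_axis @ frame.transepicondylar_axis, -1, 1)
            )
        )
        assert angle == pytest.approx(abs(retroversion_angle(bd)), abs=1e-9)

    def test_degenerate_landmarks_rejected(self):
        with pytest.raises(ValueError):
            build_anatomical_frame((0, 0, 0), 20.0, (0, 0, 1), (0, 0, 2), 10.0)

    @given(
        st.floats(-1, 1), st.floats(-1, 1), st.floats(0.2, 1.0),
        st.floats(-1, 1), st.floats(0.2, 1.0), st.floats(1.0, 20.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_axes_stay_unit_norm(self, ax, ay, az, jx, jy, bd):
        frame = build_anatomical_frame(
            (0, 0, 0), 20.0, (ax, ay, az), (jx, jy, 0.3), bd
        )
        for v in (
            frame.humeral_axis,
            frame.retroversion_axis,
            frame.transepicondylar_axis,
        ):
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-9)


class TestCapsuleGenerator:
    def test_structured_triangle_count_and_labels(self, default_capsule):
        # 2 * n_circ * n_axial triangles at the default 32 x 8 resolution
        assert default_capsule.n_elements == 2 * 32 * 8
        assert set(default_capsule.regions()) == {
            "antero_superior",
            "posterior",
            "ab_ighl",
            "pb_ighl",
            "axillary_pouch",
            LABRUM,
        }

    def test_manifold_and_positive_areas(self, default_capsule):
        default_capsule.validate()
        assert np.all(default_capsule.element_areas() > 0.0)
        counts = list(default_capsule.edge_counts().values())
        assert max(counts) == 2  # tube: interior edges shared exactly twice

    def test_rings_are_disjoint_closed_loops(self, default_capsule):
        g = set(default_capsule.node_sets["glenoid_ring"].tolist())
        h = set(default_capsule.node_sets["humeral_ring"].tolist())
        assert not (g & h)
        counts = default_capsule.edge_counts()
        for ring in (g, h):
            boundary_edges = [
                e for e, c in counts.items() if c == 1 and set(e) <= ring
            ]
            assert len(boundary_edges) == len(ring)  # a closed cycle

    def test_zero_bulge_lies_on_frustum(self, default_materials):
        params = GeometryParams(bulge=0.0)
        mesh = generate_capsule(params, default_materials)
        r = np.linalg.norm(mesh.nodes[:, :2], axis=1)
        t = mesh.nodes[:, 2] / params.length
        expected = (1 - t) * params.glenoid_radius + t * params.humeral_radius
        np.testing.assert_allclose(r, expected, atol=1e-9)

    def test_region_angular_shares(self, default_capsule):
        """Each sector's area share matches its angular share within a strip."""
        areas = default_capsule.element_areas()
        capsule_mask = default_capsule.region_of_element != LABRUM
        total = areas[capsule_mask].sum()
        spans = {"antero_superior": 3, "ab_ighl": 2, "axillary_pouch": 2,
                 "pb_ighl": 2, "posterior": 3}
        one_strip = 12.0 / 32
        for name, hours in spans.items():
            share = areas[default_capsule.region_of_element == name].sum() / total
            assert abs(share - hours / 12.0) < one_strip / 12.0 + 0.02, name

    def test_labels_rotate_with_geometry(self, default_materials):
        angle = np.radians(37.0)
        R = np.array(
            [
                [np.cos(angle), -np.sin(angle), 0],
                [np.sin(angle), np.cos(angle), 0],
                [0, 0, 1],
            ]
        )
        base = generate_capsule(GeometryParams(), default_materials)
        rotated = generate_capsule(GeometryParams(), default_materials, rotation=R)
        np.testing.assert_allclose(rotated.nodes, base.nodes @ R.T, atol=1e-12)
        assert list(rotated.region_of_element) == list(base.region_of_element)

    def test_resolution_floor_enforced(self):
        with pytest.raises(ValueError):
            GeometryParams(n_circ=4)
        with pytest.raises(ValueError):
            GeometryParams(n_axial=2)

    def test_thickness_follows_region_table(self, default_capsule, default_materials):
        for region in default_capsule.regions():
            idx = default_capsule.elements_of_region(region)
            np.testing.assert_allclose(
                default_capsule.thickness_of_element[idx],
                default_materials[region].thickness,
            )


class TestClockSectors:
    def test_cardinal_hours(self):
        hours = clock_hours([[0, 1], [1, 0], [0, -1], [-1, 0]])
        np.testing.assert_allclose(hours, [0.0, 3.0, 6.0, 9.0])

    def test_left_shoulder_mirrors_anterior(self):
        assert clock_hours([[1, 0]], handedness="left")[0] == pytest.approx(9.0)

    def test_sector_12_to_1_node_count_on_72_ring(self, default_materials):
        mesh = generate_capsule(GeometryParams(n_circ=72), default_materials)
        nodes = sector_nodes(mesh, ClockSector(12, 1))
        assert len(nodes) in (6, 7)

    def test_full_circle_selects_whole_ring(self, default_capsule):
        nodes = sector_nodes(default_capsule, ClockSector(0, 12))
        assert set(nodes.tolist()) == set(
            default_capsule.node_sets["glenoid_ring"].tolist()
        )

    def test_sector_union_identity(self, default_capsule):
        a = set(sector_nodes(default_capsule, ClockSector(11, 12)).tolist())
        b = set(sector_nodes(default_capsule, ClockSector(12, 1)).tolist())
        ab = set(sector_nodes(default_capsule, ClockSector(11, 1)).tolist())
        assert a | b == ab

    def test_selected_arc_converges_with_resolution(self, default_materials):
        sector = ClockSector(12, 1)
        shares = []
        for n in (16, 64, 256):
            mesh = generate_capsule(GeometryParams(n_circ=n), default_materials)
            shares.append(len(sector_nodes(mesh, sector)) / n)
        target = sector.span_hours / 12.0
        errs = [abs(s - target) for s in shares]
        assert errs[-1] < errs[0] and errs[-1] < 0.01

    def test_too_coarse_sector_is_an_error(self, default_materials):
        mesh = generate_capsule(GeometryParams(n_circ=8, n_axial=4), default_materials)
        with pytest.raises(ValueError, match="too coarse"):
            sector_nodes(mesh, ClockSector(12.1, 12.4))


class TestFixtures:
    def test_flat_patch_count(self):
        patch = make_fixture("flat_patch", n=5)
        assert patch.n_elements == 2 * 25
        assert patch.n_nodes == 36

    def test_thin_sphere_area_and_topology(self):
        sph = make_fixture("thin_sphere", radius=7.0, subdivisions=3)
        assert sph.element_areas().sum() == pytest.approx(
            4 * np.pi * 49.0, rel=0.01
        )
        assert all(c == 2 for c in sph.edge_counts().values())  # closed surface

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_fixture("moebius")


class TestRotation:
    def test_rodrigues_matches_matrix(self):
        rng = np.random.default_rng(7)
        v = rng.normal(size=(5, 3))
        got = rotate_about_axis(v, (0, 0, 2.0), np.pi / 2)
        expected = np.column_stack([-v[:, 1], v[:, 0], v[:, 2]])
        np.testing.assert_allclose(got, expected, atol=1e-12)
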