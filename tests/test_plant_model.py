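"""Vector-model geometry: generation, extraction, adjustment, meshing."""

import numpy as np
import pytest

from canophot.plant_model import (
    ArchitectureParams,
    LeafVectorModel,
    PlantVectorModel,
    TraitAdjustment,
    apply_adjustment,
    extract_vector_model,
    generate_synthetic_plant,
    measure_traits,
    mesh_plant,
    sample_point_cloud,
)
from canophot.pointcloud import LabeledPointCloud


def rectangular_leaf(length=60.0, width=8.0, stations=31, base=(2.0, 0.0, 20.0)):
    """Flat horizontal rectangular leaf along +x."""
    s = np.linspace(0, length, stations)
    axis = np.column_stack([base[0] + s, np.full_like(s, base[1]),
                            np.full_like(s, base[2])])
    half = np.zeros((stations, 3))
    half[:, 1] = width / 2
    return LeafVectorModel(axis=axis, half_left=half, half_right=-half,
                           layer=2, leaf_index=1)


def one_leaf_plant(leaf):
    stem = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, max(leaf.base[2], 1.0)]])
    return PlantVectorModel(leaves=[leaf], stem=stem, stem_radius=1.0)


class TestMeasure:
    def test_rectangle_traits(self):
        plant = one_leaf_plant(rectangular_leaf())
        table, summary = measure_traits(plant)
        row = table.iloc[0]
        assert row.length_cm == pytest.approx(60.0, rel=1e-9)
        assert row.width_cm == pytest.approx(8.0, rel=1e-9)
        assert row.base_height_cm == pytest.approx(20.0)
        assert row.area_cm2 == pytest.approx(480.0, rel=0.02)

    def test_base_heights_exact(self):
        leaves = []
        for i, z in enumerate((10.0, 30.0, 50.0), start=1):
            leaf = rectangular_leaf(base=(2.0, 0.0, z))
            leaf.leaf_index = i
            leaves.append(leaf)
        plant = PlantVectorModel(leaves=leaves,
                                 stem=np.array([[0, 0, 0], [0, 0, 55.0]]))
        table, _ = measure_traits(plant)
        np.testing.assert_allclose(sorted(table.base_height_cm), [10, 30, 50])

    def test_quarter_circle_arc_length(self):
        r, stations = 40.0, 201
        th = np.linspace(0, np.pi / 2, stations)
        axis = np.column_stack([r * np.sin(th), np.zeros(stations),
                                50.0 - r * (1 - np.cos(th))])
        half = np.zeros((stations, 3))
        half[:, 1] = 3.0
        plant = one_leaf_plant(LeafVectorModel(axis, half, -half, 2, 1))
        table, _ = measure_traits(plant)
        assert table.iloc[0].length_cm == pytest.approx(2 * np.pi * r / 4, rel=0.02)


class TestMesh:
    def test_rectangle_area(self):
        mesh = mesh_plant(one_leaf_plant(rectangular_leaf()))
        leaf_area = mesh.facet_area[mesh.facet_leaf == 1].sum()
        assert leaf_area == pytest.approx(480.0, rel=0.01)

    def test_identity_adjustment_mesh_identical(self, erect_plant):
        m1 = mesh_plant(erect_plant)
        m2 = mesh_plant(apply_adjustment(erect_plant, TraitAdjustment()))
        np.testing.assert_array_equal(m1.vertices, m2.vertices)
        np.testing.assert_array_equal(m1.triangles, m2.triangles)

    def test_station_refinement_converges(self):
        p1 = generate_synthetic_plant(
            ArchitectureParams(n_leaves=3, curvature_deg=80.0, stations=31),
            rng_seed=0)
        p2 = generate_synthetic_plant(
            ArchitectureParams(n_leaves=3, curvature_deg=80.0, stations=62),
            rng_seed=0)
        a1 = mesh_plant(p1).leaf_area_cm2
        a2 = mesh_plant(p2).leaf_area_cm2
        assert abs(a2 - a1) / a1 < 0.005

    def test_no_degenerate_facets(self, erect_plant):
        mesh = mesh_plant(erect_plant)
        assert (mesh.facet_area >= 1e-4).all()


class TestGenerate:
    def test_erect_preset_angles(self):
        plant = generate_synthetic_plant("erect", rng_seed=1)
        for leaf in plant.leaves:
            t0 = leaf.axis[1] - leaf.axis[0]
            angle = np.degrees(np.arccos(t0[2] / np.linalg.norm(t0)))
            assert angle <= 30.0

    def test_determinism(self):
        p1 = generate_synthetic_plant("spread", rng_seed=9)
        p2 = generate_synthetic_plant("spread", rng_seed=9)
        for l1, l2 in zip(p1.leaves, p2.leaves):
            np.testing.assert_array_equal(l1.axis, l2.axis)

    def test_flat_leaf_area_matches_shape_factor(self):
        params = ArchitectureParams(
            n_leaves=12, leaf_length_cm=60, leaf_width_cm=8,
            insertion_angle_deg=85.0, curvature_deg=0.0,
            length_jitter=0.0, width_jitter=0.0, angle_jitter_deg=0.0,
            length_profile="uniform",
        )
        plant = generate_synthetic_plant(params, rng_seed=0)
        # shape factor of the maize width profile, computed by quadrature
        s = np.linspace(0, 1, 2001)
        shape = np.trapezoid(np.sin(np.pi * s**0.7) ** 0.8, s)
        expected = 12 * 60 * 8 * shape
        assert mesh_plant(plant).leaf_area_cm2 == pytest.approx(expected, rel=0.05)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="invalid parameters"):
            generate_synthetic_plant(
                ArchitectureParams(leaf_length_cm=-5.0), rng_seed=0
            )

    def test_layer_assignment_by_base_height(self):
        plant = generate_synthetic_plant("erect", rng_seed=3)
        top = max(leaf.axis[:, 2].max() for leaf in plant.leaves)
        for leaf in plant.leaves:
            expected = 1 if leaf.base[2] < top / 2 else 2
            assert leaf.layer == expected


class TestAdjust:
    def test_identity_traits_unchanged(self, erect_plant):
        adjusted = apply_adjustment(erect_plant, TraitAdjustment())
        t0, _ = measure_traits(erect_plant)
        t1, _ = measure_traits(adjusted)
        np.testing.assert_allclose(t1.length_cm, t0.length_cm)
        np.testing.assert_allclose(t1.width_cm, t0.width_cm)

    def test_length_doubles_width_fixed(self):
        plant = one_leaf_plant(rectangular_leaf())
        out = apply_adjustment(plant, TraitAdjustment(leaf_length_factor=2.0))
        table, _ = measure_traits(out)
        assert table.iloc[0].length_cm == pytest.approx(120.0)
        assert table.iloc[0].width_cm == pytest.approx(8.0)

    def test_length_composability(self, erect_plant):
        a = apply_adjustment(
            apply_adjustment(erect_plant, TraitAdjustment(leaf_length_factor=1.2)),
            TraitAdjustment(leaf_length_factor=1.5),
        )
        b = apply_adjustment(erect_plant, TraitAdjustment(leaf_length_factor=1.8))
        ta, _ = measure_traits(a)
        tb, _ = measure_traits(b)
        np.testing.assert_allclose(ta.length_cm, tb.length_cm, rtol=1e-9)

    def test_angle_rotation_flattens_vertical_leaf(self):
        # vertical straight leaf along +z
        stations = 31
        s = np.linspace(0, 60, stations)
        axis = np.column_stack([np.full_like(s, 2.0), np.zeros_like(s), 30.0 + s])
        half = np.zeros((stations, 3))
        half[:, 1] = 4.0
        plant = one_leaf_plant(LeafVectorModel(axis, half, -half, 2, 1))
        out = apply_adjustment(plant, TraitAdjustment(leaf_angle_delta_deg=-90.0))
        leaf = out.leaves[0]
        # tip now horizontal at base height; ground footprint = length x width
        assert abs(leaf.axis[-1, 2] - leaf.axis[0, 2]) < 1e-6
        dxy = np.linalg.norm(leaf.axis[-1, :2] - leaf.axis[0, :2])
        assert dxy == pytest.approx(60.0, rel=1e-9)
        footprint = dxy * (np.linalg.norm(leaf.half_left[0])
                           + np.linalg.norm(leaf.half_right[0]))
        assert footprint == pytest.approx(60.0 * 8.0, rel=0.02)

    def test_positive_angle_is_more_erect(self, erect_plant):
        out = apply_adjustment(erect_plant, TraitAdjustment(leaf_angle_delta_deg=10.0))
        for before, after in zip(erect_plant.leaves, out.leaves):
            assert after.axis[-1, 2] > before.axis[-1, 2] - 1e-9

    def test_curvature_bends_total_angle(self):
        plant = one_leaf_plant(rectangular_leaf())
        out = apply_adjustment(plant, TraitAdjustment(leaf_curvature_delta_deg=90.0))
        leaf = out.leaves[0]
        t_first = leaf.axis[1] - leaf.axis[0]
        t_last = leaf.axis[-1] - leaf.axis[-2]
        cos = t_first @ t_last / (np.linalg.norm(t_first) * np.linalg.norm(t_last))
        turn = np.degrees(np.arccos(np.clip(cos, -1, 1)))
        assert turn == pytest.approx(90.0, abs=4.0)
        # droop: tip below the flat leaf's tip
        assert leaf.axis[-1, 2] < plant.leaves[0].axis[-1, 2]
        # arc length preserved
        assert leaf.length == pytest.approx(plant.leaves[0].length, rel=1e-9)

    def test_leaf_number_add_remove(self, erect_plant):
        n = len(erect_plant.leaves)
        more = apply_adjustment(erect_plant, TraitAdjustment(leaf_number_delta=3))
        fewer = apply_adjustment(erect_plant, TraitAdjustment(leaf_number_delta=-2))
        assert len(more.leaves) == n + 3
        assert len(fewer.leaves) == n - 2
        # clones stack above the original top
        top_orig = max(leaf.base[2] for leaf in erect_plant.leaves)
        new_bases = sorted(leaf.base[2] for leaf in more.leaves)[-3:]
        assert all(b > top_orig for b in new_bases)
        # removal takes the lowest leaves
        min_before = min(leaf.base[2] for leaf in erect_plant.leaves)
        assert min(leaf.base[2] for leaf in fewer.leaves) > min_before

    def test_removing_all_leaves_errors(self, erect_plant):
        with pytest.raises(ValueError, match="no leaves left"):
            apply_adjustment(
                erect_plant,
                TraitAdjustment(leaf_number_delta=-len(erect_plant.leaves)),
            )


class TestExtract:
    def test_rectangle_recovery(self):
        plant = one_leaf_plant(rectangular_leaf(base=(2.0, 0.0, 30.0)))
        cloud = sample_point_cloud(plant, points_per_cm2=25.0, rng_seed=0)
        rec = extract_vector_model(cloud, stations=31)
        table, _ = measure_traits(rec)
        assert table.iloc[0].length_cm == pytest.approx(60.0, rel=0.02)
        assert table.iloc[0].width_cm == pytest.approx(8.0, rel=0.05)

    def test_vertical_leaf_monotone_axis(self):
        stations = 31
        s = np.linspace(0, 50, stations)
        axis = np.column_stack([np.full_like(s, 2.0), np.zeros_like(s), 10.0 + s])
        half = np.zeros((stations, 3))
        half[:, 1] = 3.0
        plant = one_leaf_plant(LeafVectorModel(axis, half, -half, 2, 1))
        cloud = sample_point_cloud(plant, points_per_cm2=20.0, rng_seed=1)
        rec = extract_vector_model(cloud, stations=21)
        z = rec.leaves[0].axis[:, 2]
        assert np.all(np.diff(z) > -0.5)
        assert z[-1] - z[0] > 45.0

    def test_fragmented_leaf_errors(self):
        rng = np.random.default_rng(0)
        a = rng.random((150, 3)) * 5
        b = rng.random((150, 3)) * 5 + np.array([100, 0, 0])
        cloud = LabeledPointCloud(np.vstack([a, b]), np.ones(300, np.int64))
        with pytest.raises(ValueError, match="fragmented leaf"):
            extract_vector_model(cloud)

    def test_too_few_points_is_degenerate(self):
        rng = np.random.default_rng(0)
        cloud = LabeledPointCloud(rng.random((50, 3)), np.ones(50, np.int64))
        with pytest.raises(ValueError, match="degenerate leaf"):
            extract_vector_model(cloud)

    def test_full_plant_round_trip(self, erect_plant):
        """Generator -> cloud -> extraction recovers the architecture."""
        cloud = sample_point_cloud(erect_plant, points_per_cm2=25.0,
                                   noise_sigma_cm=0.05, rng_seed=3)
        rec = extract_vector_model(cloud, stations=31)
        t0, _ = measure_traits(erect_plant)
        t1, _ = measure_traits(rec)
        m = t0.merge(t1, on="leaf", suffixes=("_true", "_rec"))
        len_err = np.abs(m.length_cm_rec / m.length_cm_true - 1)
        wid_err = np.abs(m.width_cm_rec / m.width_cm_true - 1)
        base_err = np.abs(m.base_height_cm_rec - m.base_height_cm_true) / m.base_height_cm_true
        assert len_err.max() < 0.03
        assert wid_err.max() < 0.08
        assert base_err.max() < 0.03
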