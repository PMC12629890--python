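import numpy as np
import pytest

from stncoalign.coalign import (
    CoalignmentBounds,
    CoalignOptions,
    RecordingSite,
    alignment_cost,
    apply_coalignment,
    coalign,
    sites_to_arrays,
)
from stncoalign.geometry import (
    TriangleMesh,
    distance_to_surface,
    mesh_centroid,
    point_in_mesh,
    scale_mesh,
)
from stncoalign.metrics import Trajectory
from stncoalign.synthetic import make_scene

from conftest import cube_mesh


def scene_sites(scene):
    return [
        RecordingSite(p, int(l), str(c), float(d))
        for p, l, c, d in zip(scene.site_positions, scene.site_labels,
                              scene.site_channels, scene.site_depths)
    ]


def naive_cost_oracle(sites, mesh, s, alpha, center):
    """Per-site loop built only from the two geometric primitives."""
    scaled = scale_mesh(mesh, alpha, center)
    total = 0.0
    for site in sites:
        q = site.position - np.asarray(s, dtype=float)
        member = int(point_in_mesh(q, scaled))
        if member != site.label:
            total += distance_to_surface(q, scaled)
    return total / len(sites)


class TestAlignmentCost:
    def test_consistent_labels_zero_cost(self, cube):
        sites = [
            RecordingSite([0.0, 0, 0], 1),
            RecordingSite([0.2, 0.1, 0], 1),
            RecordingSite([2.0, 0, 0], 0),
        ]
        assert alignment_cost(sites, cube, np.zeros(3), 1.0) == 0.0

    def test_single_disagreement_forced_value(self, cube):
        # one disagreeing site at distance 2.0 from the surface, N=4
        sites = [
            RecordingSite([0.0, 0, 0], 1),
            RecordingSite([0.3, 0, 0], 1),
            RecordingSite([3.0, 0, 0], 0),
            RecordingSite([2.5, 0.0, 0.0], 1),  # outside, labelled inside
        ]
        cost = alignment_cost(sites, cube, np.zeros(3), 1.0, (0.0, 0, 0))
        assert cost == pytest.approx(2.0 / 4.0, abs=1e-12)

    def test_oracle_equivalence_random_scenes(self):
        rng = np.random.default_rng(0)
        for k in range(10):
            scene = make_scene(seed=k, true_shift=rng.uniform(-2, 2, 3),
                               true_scale=rng.uniform(0.85, 1.15),
                               label_noise_rate=0.05)
            sites = scene_sites(scene)
            for _ in range(3):
                s = rng.uniform(-2, 2, size=3)
                alpha = rng.uniform(0.8, 1.2)
                ours = alignment_cost(sites, scene.mesh, s, alpha,
                                      scene.scale_center)
                oracle = naive_cost_oracle(sites, scene.mesh, s, alpha,
                                           scene.scale_center)
                assert ours == pytest.approx(oracle, abs=1e-12)

    def test_translation_equivariance(self, cube):
        rng = np.random.default_rng(1)
        sites = [RecordingSite(rng.uniform(-1, 1, 3), int(rng.integers(2)))
                 for _ in range(20)]
        t = np.array([0.7, -0.3, 1.1])
        moved_mesh = TriangleMesh(cube.vertices + t, cube.faces)
        moved_sites = [
            RecordingSite(s.position + t, s.label) for s in sites
        ]
        for _ in range(5):
            s = rng.uniform(-1, 1, 3)
            alpha = rng.uniform(0.8, 1.2)
            c0 = alignment_cost(sites, cube, s, alpha, (0.0, 0.0, 0.0))
            c1 = alignment_cost(moved_sites, moved_mesh, s, alpha, t)
            assert c0 == pytest.approx(c1, abs=1e-12)

    def test_invalid_inputs(self, cube):
        site = RecordingSite([0.0, 0, 0], 1)
        with pytest.raises(ValueError):
            alignment_cost([], cube, np.zeros(3), 1.0)
        with pytest.raises(ValueError):
            alignment_cost([site], cube, np.zeros(3), -1.0)
        open_mesh = TriangleMesh(cube.vertices, cube.faces[:-1])
        with pytest.raises(ValueError, match="validation"):
            alignment_cost([site], open_mesh, np.zeros(3), 1.0)


class TestCoalign:
    def test_identity_scene_returns_identity(self):
        scene = make_scene(seed=0)
        result = coalign(scene_sites(scene), scene.mesh)
        np.testing.assert_allclose(result.shift, 0.0, atol=1e-6)
        assert result.scale == pytest.approx(1.0, abs=1e-6)
        assert result.cost_final == 0.0

    def test_invariants_on_noisy_scene(self):
        scene = make_scene(seed=3, true_shift=(1.5, -0.5, 1.0),
                           true_scale=1.1, label_noise_rate=0.15)
        bounds = CoalignmentBounds()
        result = coalign(scene_sites(scene), scene.mesh, bounds,
                         CoalignOptions(max_evaluations=600, ftol=1e-6))
        assert np.linalg.norm(result.shift) <= bounds.max_shift_norm + 1e-9
        assert bounds.scale_range[0] <= result.scale <= bounds.scale_range[1]
        assert result.cost_final <= result.cost_initial
        # reported final cost equals the cost evaluated at the estimate
        check = alignment_cost(scene_sites(scene), scene.mesh, result.shift,
                               result.scale, result.scale_center)
        assert result.cost_final == pytest.approx(check, abs=1e-12)

    def test_parameter_recovery_small_sample(self):
        # the full 50-scene protocol lives in the acceptance suite
        hits = 0
        rng = np.random.default_rng(7)
        for k in range(5):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            s_true = u * rng.uniform(0.5, 2.5)
            a_true = rng.uniform(0.85, 1.15)
            scene = make_scene(seed=200 + k, true_shift=s_true,
                               true_scale=a_true)
            result = coalign(
                scene_sites(scene), scene.mesh,
                options=CoalignOptions(multistart=True, n_grid=5, ftol=1e-6,
                                       max_evaluations=1000,
                                       refine_plateau=True),
            )
            if (np.linalg.norm(result.shift - s_true) <= 0.5
                    and abs(result.scale - a_true) <= 0.05):
                hits += 1
        assert hits >= 4

    def test_single_class_warns(self, cube):
        sites = [RecordingSite([0.0, 0, 0], 1), RecordingSite([0.1, 0, 0], 1)]
        with pytest.warns(UserWarning, match="single label"):
            coalign(sites, cube, options=CoalignOptions(max_evaluations=50))

    def test_zero_width_scale_range_rejected(self):
        with pytest.raises(ValueError):
            CoalignmentBounds(scale_range=(1.0, 1.0))
        with pytest.raises(ValueError):
            CoalignmentBounds(scale_range=(1.1, 1.2))
        with pytest.raises(ValueError):
            CoalignmentBounds(max_shift_norm=0.0)


class TestApplyCoalignment:
    def test_identity_result_unchanged(self):
        scene = make_scene(seed=1)
        sites = scene_sites(scene)
        result = coalign(sites, scene.mesh,
                         options=CoalignOptions(max_evaluations=50))
        result.shift = np.zeros(3)
        result.scale = 1.0
        new_sites, new_traj, new_mesh = apply_coalignment(
            sites, scene.trajectories, scene.mesh, result
        )
        for a, b in zip(sites, new_sites):
            np.testing.assert_array_equal(a.position, b.position)
        np.testing.assert_array_equal(new_mesh.vertices, scene.mesh.vertices)

    def test_roundtrip_invertibility(self):
        scene = make_scene(seed=2, true_shift=(1.0, 0.5, -0.5), true_scale=1.1)
        sites = scene_sites(scene)
        result = coalign(sites, scene.mesh,
                         options=CoalignOptions(max_evaluations=300, ftol=1e-6))
        moved, traj, mesh2 = apply_coalignment(
            sites, scene.trajectories, scene.mesh, result
        )
        # invert
        inverse = type(result)(
            shift=-result.shift, scale=1.0 / result.scale,
            cost_initial=0, cost_final=0, regularized_initial=0,
            regularized_final=0, n_evaluations=0, converged=True,
            scale_center=result.scale_center,
        )
        back, _, mesh3 = apply_coalignment(moved, traj, mesh2, inverse)
        for a, b in zip(sites, back):
            np.testing.assert_allclose(a.position, b.position, atol=1e-12)
        np.testing.assert_allclose(mesh3.vertices, scene.mesh.vertices,
                                   atol=1e-12)

    def test_transformed_scene_cost_equals_final(self):
        scene = make_scene(seed=5, true_shift=(0.8, -1.2, 0.3),
                           true_scale=0.9, label_noise_rate=0.1)
        sites = scene_sites(scene)
        result = coalign(sites, scene.mesh,
                         options=CoalignOptions(max_evaluations=300, ftol=1e-6))
        new_sites, _, new_mesh = apply_coalignment(
            sites, None, scene.mesh, result
        )
        replay = alignment_cost(new_sites, new_mesh, np.zeros(3), 1.0,
                                result.scale_center)
        assert replay == pytest.approx(result.cost_final, abs=1e-12)

    def test_trajectories_translated(self):
        scene = make_scene(seed=6)
        sites = scene_sites(scene)
        result = coalign(sites, scene.mesh,
                         options=CoalignOptions(max_evaluations=50))
        result.shift = np.array([1.0, -2.0, 0.5])
        _, new_traj, _ = apply_coalignment(
            sites, scene.trajectories, scene.mesh, result
        )
        for name, t in scene.trajectories.items():
            np.testing.assert_allclose(
                new_traj[name].anchor, t.anchor - result.shift, atol=1e-15
            )
            np.testing.assert_array_equal(new_traj[name].direction, t.direction)


class TestRecordingSite:
    def test_invalid_site_rejected(self):
        with pytest.raises(ValueError):
            RecordingSite([np.inf, 0, 0], 1)
        with pytest.raises(ValueError):
            RecordingSite([0.0, 0, 0], 2)

    def test_sites_to_arrays(self):
        sites = [RecordingSite([1.0, 2, 3], 1), RecordingSite([4.0, 5, 6], 0)]
        pos, lab = sites_to_arrays(sites)
        assert pos.shape == (2, 3)
        np.testing.assert_array_equal(lab, [1, 0])
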