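import math

import numpy as np
import pytest
from conftest import make_candidates
from _oracles import (
    brute_force_min_pair,
    scalar_aperture,
    scalar_force_closure,
    scalar_nga,
    scalar_normalize,
    scalar_torque,
    scalar_visibility,
)

import graspsel as gs
from graspsel.object_model import rotation_about_axis
from graspsel.penalty_maps import load_map, save_map


class TestModelConfig:
    def test_nga_vector_unit_normalized(self, config):
        assert np.linalg.norm(config.nga_vector) == pytest.approx(1.0)
        # direction preserved: printed components scale by 1/0.9985...
        assert config.nga_vector[0] / config.nga_vector[1] == pytest.approx(
            0.49 / 0.87
        )

    def test_zero_nga_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            gs.ModelConfig(nga_vector=[0, 0, 0])

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError, match="aperture"):
            gs.ModelConfig(aperture_threshold=0)

    def test_yaml_roundtrip_and_stable_hash(self, tmp_path, config):
        path = tmp_path / "cfg.yaml"
        config.to_yaml(path)
        loaded = gs.ModelConfig.from_yaml(path)
        np.testing.assert_allclose(loaded.nga_vector, config.nga_vector)
        assert loaded.hash() == config.hash()


class TestForceClosure:
    def test_opposed_parallel_faces_zero_penalty(self):
        cands = make_candidates(
            [[0, 0, 10], [25, 0, 10]], [[-1, 0, 0], [1, 0, 0]]
        )
        m = gs.penalty_force_closure(cands)
        assert m.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_same_planar_face_penalty_pi(self):
        # both contacts on one flat face: axis perpendicular to both forces
        cands = make_candidates(
            [[0, 0, 10], [25, 0, 10]], [[0, 0, 1], [0, 0, 1]]
        )
        m = gs.penalty_force_closure(cands)
        assert m.values[0, 1] == pytest.approx(math.pi, abs=1e-12)

    def test_lateral_offset_formula(self):
        # opposed faces 25 mm apart, 10 mm lateral offset
        cands = make_candidates(
            [[0, 0, 10], [25, 10, 10]], [[-1, 0, 0], [1, 0, 0]]
        )
        m = gs.penalty_force_closure(cands)
        assert m.values[0, 1] == pytest.approx(2 * math.atan(10 / 25), abs=1e-12)

    def test_range_and_diagonal_mask(self, l_candidates):
        m = gs.penalty_force_closure(l_candidates)
        vals = m.unmasked()
        assert vals.min() >= 0 and vals.max() <= 2 * math.pi + 1e-12
        assert np.all(np.diag(m.mask))


class TestTorque:
    def test_midpoint_at_com_zero_torque(self, bar_object, config):
        com = bar_object.com
        cands = make_candidates(
            [com + [0, -30, 5], com - [0, -30, 5]], [[0, -1, 0], [0, 1, 0]]
        )
        m = gs.penalty_torque(cands, bar_object, config)
        assert m.values[0, 1] == pytest.approx(0.0, abs=1e-15)

    def test_offset_50mm_hand_computed(self, bar_object, config):
        com = bar_object.com
        cands = make_candidates(
            [com + [50, 0, 0], com + [50, 0, 0.001]], [[0, -1, 0], [0, 1, 0]]
        )
        m = gs.penalty_torque(cands, bar_object, config)
        # ~2 * m * g * 0.05 N*m with both levers 50 mm along x
        assert m.values[0, 1] == pytest.approx(2 * 0.097 * 9.81 * 0.05, rel=1e-4)

    def test_vertical_displacement_zero(self, bar_object, config):
        com = bar_object.com
        cands = make_candidates(
            [com + [0, 0, 40], com + [0, 0, -40]], [[0, -1, 0], [0, 1, 0]]
        )
        m = gs.penalty_torque(cands, bar_object, config)
        assert m.values[0, 1] == pytest.approx(0.0, abs=1e-15)


class TestNGA:
    def test_parallel_zero(self, config):
        p0 = np.zeros(3)
        p1 = config.nga_vector * 30
        cands = make_candidates([p0, p1], [[0, 0, 1], [0, 0, 1]])
        m = gs.penalty_nga(cands, config)
        assert m.values[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_antiparallel_pi(self, config):
        p0 = np.zeros(3)
        p1 = config.nga_vector * 30
        cands = make_candidates([p0, p1], [[0, 0, 1], [0, 0, 1]])
        m = gs.penalty_nga(cands, config)
        assert m.values[1, 0] == pytest.approx(math.pi, abs=1e-9)

    def test_perpendicular_horizontal_half_pi(self, config):
        perp = np.array([-config.nga_vector[1], config.nga_vector[0], 0.0])
        cands = make_candidates([np.zeros(3), perp * 30], [[0, 0, 1], [0, 0, 1]])
        m = gs.penalty_nga(cands, config)
        assert m.values[0, 1] == pytest.approx(math.pi / 2, abs=1e-9)

    def test_swap_identity(self, l_candidates, config):
        m = gs.penalty_nga(l_candidates, config)
        off = ~np.eye(m.n, dtype=bool)
        np.testing.assert_allclose((m.values + m.values.T)[off], math.pi,
                                   atol=1e-9)


class TestAperture:
    @pytest.mark.parametrize("aperture,expected", [(20, 0.0), (25, 0.0), (40, 15.0)])
    def test_threshold_examples(self, aperture, expected, config):
        cands = make_candidates(
            [[0, 0, 10], [aperture, 0, 10]], [[-1, 0, 0], [1, 0, 0]]
        )
        m = gs.penalty_aperture(cands, config)
        assert m.values[0, 1] == pytest.approx(expected, abs=1e-12)
        assert m.values[1, 0] == pytest.approx(expected, abs=1e-12)


class TestVisibility:
    def _grid(self):
        # 4x4 grid in the horizontal plane, z arbitrary
        xs, ys = np.meshgrid(np.arange(4) * 10.0, np.arange(4) * 10.0)
        pts = np.column_stack([xs.ravel(), ys.ravel(), np.full(16, 5.0)])
        return make_candidates(pts, np.tile([0, 0, 1.0], (16, 1)))

    def test_line_beyond_hand_side_extreme_zero(self):
        cands = self._grid()
        cfg = gs.ModelConfig(hand_reference_point=[15, -100, 0])
        m = gs.penalty_visibility(cands, cfg)
        # contacts on the y=0 row: nothing lies strictly on the hand side
        i = 0  # (0, 0)
        j = 3  # (30, 0)
        assert m.values[i, j] == 0.0

    def test_all_other_candidates_on_hand_side(self):
        cands = self._grid()
        cfg = gs.ModelConfig(hand_reference_point=[15, -100, 0])
        m = gs.penalty_visibility(cands, cfg)
        # contacts on the far row y=30: the 12 points strictly nearer the
        # hand are occluded (the 2 other y=30 points lie on the line)
        i, j = 12, 15
        assert m.values[i, j] == pytest.approx(12 / 16)

    def test_point_symmetric_set_half_occluded(self):
        rng = np.random.default_rng(4)
        half = rng.normal(size=(20, 2)) * 30
        pts2 = np.vstack([half, -half])
        pts = np.column_stack([pts2, np.full(40, 5.0)])
        cands = make_candidates(pts, np.tile([0, 0, 1.0], (40, 1)))
        cfg = gs.ModelConfig(hand_reference_point=[0, -200, 0])
        m = gs.penalty_visibility(cands, cfg)
        # grasp line through the centroid: points 0 and 20 are antipodal
        n = 40
        assert m.values[0, 20] == pytest.approx(0.5, abs=1 / n + 1e-9)

    def test_degenerate_projection_uses_hand_perpendicular(self):
        # two candidates stacked vertically project to the same 2D point
        pts = [[0, 0, 5], [0, 0, 30], [0, 20, 5], [0, -20, 5]]
        cands = make_candidates(pts, np.tile([1.0, 0, 0], (4, 1)))
        cfg = gs.ModelConfig(hand_reference_point=[0, -100, 0])
        m = gs.penalty_visibility(cands, cfg)
        # line perpendicular to hand direction (+y): only y = -20 occluded
        assert m.values[0, 1] == pytest.approx(1 / 4)

    def test_values_in_unit_range(self, l_candidates, config):
        m = gs.penalty_visibility(l_candidates, config)
        assert m.unmasked().min() >= 0.0
        assert m.unmasked().max() <= 1.0


class TestNormalizeMap:
    def _map(self, values, label="FC"):
        values = np.asarray(values, float)
        return gs.PenaltyMap(values, np.eye(len(values), dtype=bool), False, label)

    def test_minmax_rescale(self):
        raw = [[0, 2, 4], [2, 0, 6], [4, 6, 0]]
        m = gs.normalize_map(self._map(raw))
        # off-diagonal entries {2, 4, 6} -> {0, 0.5, 1}
        assert m.values[0, 1] == pytest.approx(0.0)
        assert m.values[0, 2] == pytest.approx(0.5)
        assert m.values[1, 2] == pytest.approx(1.0)
        assert scalar_normalize([2.0, 4.0, 6.0]) == [0.0, 0.5, 1.0]

    def test_constant_map_all_zeros(self):
        m = gs.normalize_map(self._map(np.full((3, 3), 7.0)))
        assert np.all(m.values == 0.0)
        assert m.normalized

    def test_idempotent(self, l_candidates, config):
        m = gs.normalize_map(gs.penalty_nga(l_candidates, config))
        again = gs.normalize_map(m)
        np.testing.assert_allclose(again.values, m.values, atol=1e-15)

    def test_masked_entries_ignored(self):
        vals = np.array([[99.0, 1.0], [3.0, 99.0]])
        mask = np.eye(2, dtype=bool)
        m = gs.normalize_map(gs.PenaltyMap(vals, mask, False, "T"))
        assert m.values[0, 1] == 0.0 and m.values[1, 0] == 1.0


class TestCombine:
    def test_single_weight_equals_squared_map(self, l_maps):
        w = gs.WeightVector(1, 0, 0, 0, 0)
        combined = gs.combine(l_maps, w)
        np.testing.assert_allclose(combined.values, l_maps[0].values ** 2,
                                   atol=1e-15)

    def test_all_zero_pair_stays_zero(self, l_maps, l_overall):
        stack = np.stack([m.values for m in l_maps])
        zero_pairs = (stack == 0).all(axis=0) & ~l_overall.mask
        if zero_pairs.any():
            assert np.all(l_overall.values[zero_pairs] == 0.0)

    def test_unweighted_combination_normalized(self, l_overall):
        vals = l_overall.unmasked()
        assert vals.min() == pytest.approx(0.0)
        assert vals.max() == pytest.approx(1.0)

    def test_unnormalized_input_rejected(self, l_candidates, l_maps, config):
        raw = gs.penalty_nga(l_candidates, config)
        with pytest.raises(ValueError, match="not normalized"):
            gs.combine([raw] + list(l_maps[1:]))

    def test_mismatched_candidate_sets_rejected(self, l_maps):
        small = gs.PenaltyMap(np.zeros((3, 3)), np.eye(3, dtype=bool), True, "FC")
        with pytest.raises(ValueError, match="different candidate"):
            gs.combine([small] + list(l_maps[1:]))

    def test_minimum_matches_brute_force_scan(self, l_overall):
        pair, value = brute_force_min_pair(
            l_overall.values.tolist(), l_overall.mask.tolist()
        )
        masked = np.where(l_overall.mask, np.inf, l_overall.values)
        assert value == masked.min()
        assert masked[pair] == value


@pytest.fixture(scope="module")
def small(config):
    obj = gs.build_polycube([(0, 0, 0), (1, 0, 0), (1, 1, 0)],
                            resolution="coarse", name="tromino")
    cands = gs.candidate_contacts(obj, config.table_z)
    assert cands.n <= 50
    return obj, cands


class TestScalarOracleEquivalence:
    """Vectorized maps equal a per-pair scalar loop to 1e-9."""

    def _check(self, m, oracle):
        n = m.n
        for i in range(n):
            for j in range(n):
                if i == j:
                    assert m.mask[i, j]
                    continue
                assert m.values[i, j] == pytest.approx(oracle(i, j), abs=1e-9)

    def test_force_closure(self, small):
        _, cands = small
        m = gs.penalty_force_closure(cands)
        pos, nrm = cands.positions.tolist(), cands.normals.tolist()
        self._check(m, lambda i, j: scalar_force_closure(pos, nrm, i, j))

    def test_torque(self, small, config):
        obj, cands = small
        m = gs.penalty_torque(cands, obj, config)
        pos, com = cands.positions.tolist(), obj.com.tolist()
        self._check(
            m, lambda i, j: scalar_torque(pos, com, obj.mass, config.gravity, i, j)
        )

    def test_nga(self, small, config):
        _, cands = small
        m = gs.penalty_nga(cands, config)
        pos, nga = cands.positions.tolist(), config.nga_vector.tolist()
        self._check(m, lambda i, j: scalar_nga(pos, nga, i, j))

    def test_aperture(self, small, config):
        _, cands = small
        m = gs.penalty_aperture(cands, config)
        pos = cands.positions.tolist()
        self._check(
            m, lambda i, j: scalar_aperture(pos, config.aperture_threshold, i, j)
        )

    def test_visibility(self, small, config):
        _, cands = small
        m = gs.penalty_visibility(cands, config)
        pos = cands.positions.tolist()
        hand = config.hand_reference_point.tolist()
        self._check(m, lambda i, j: scalar_visibility(pos, hand, i, j))

    def test_combined(self, small, config):
        obj, cands = small
        maps = gs.compute_penalty_maps(cands, obj, config)
        overall = gs.combine(maps)
        raw = [
            gs.penalty_force_closure(cands),
            gs.penalty_torque(cands, obj, config),
            gs.penalty_nga(cands, config),
            gs.penalty_aperture(cands, config),
            gs.penalty_visibility(cands, config),
        ]
        # scalar route: normalize each raw channel, sum, renormalize
        total = np.zeros_like(overall.values)
        for m in raw:
            flat = m.values[~m.mask].tolist()
            normed = scalar_normalize(flat)
            tmp = np.zeros_like(m.values)
            tmp[~m.mask] = normed
            total += tmp
        flat = scalar_normalize(total[~overall.mask].tolist())
        expected = np.zeros_like(total)
        expected[~overall.mask] = flat
        np.testing.assert_allclose(overall.values, expected, atol=1e-9)


class TestInvariances:
    def test_symmetric_maps(self, l_candidates, l_object, config):
        for fn in (
            lambda: gs.penalty_force_closure(l_candidates),
            lambda: gs.penalty_torque(l_candidates, l_object, config),
            lambda: gs.penalty_aperture(l_candidates, config),
        ):
            m = fn()
            np.testing.assert_allclose(m.values, m.values.T, atol=1e-12)

    def test_normalized_maps_in_unit_interval(self, l_maps):
        for m in l_maps:
            assert m.normalized
            assert m.unmasked().min() >= 0.0
            assert m.unmasked().max() <= 1.0

    def test_positive_rescaling_absorbed_by_normalization(self, l_candidates,
                                                          config):
        m = gs.penalty_aperture(l_candidates, config)
        scaled = gs.PenaltyMap(m.values * 3.7, m.mask, False, m.label)
        np.testing.assert_allclose(
            gs.normalize_map(m).values, gs.normalize_map(scaled).values,
            atol=1e-12,
        )

    def test_torque_nga_visibility_translation_invariant(self, l_object, config):
        shifted = l_object.with_pose(
            gs.RigidTransform(np.eye(3), [37.0, -12.0, 0.0])
        )
        cfg_shifted = gs.ModelConfig(
            hand_reference_point=config.hand_reference_point + [37.0, -12.0, 0.0]
        )
        c0 = gs.candidate_contacts(l_object)
        c1 = gs.candidate_contacts(shifted)
        for f0, f1 in [
            (gs.penalty_torque(c0, l_object, config),
             gs.penalty_torque(c1, shifted, config)),
            (gs.penalty_nga(c0, config), gs.penalty_nga(c1, config)),
            (gs.penalty_visibility(c0, config),
             gs.penalty_visibility(c1, cfg_shifted)),
        ]:
            np.testing.assert_allclose(f0.values, f1.values, atol=1e-9)

    def test_nga_not_rotation_invariant(self, l_object, config):
        rotated = l_object.with_pose(
            gs.RigidTransform(rotation_about_axis("z", 90.0), np.zeros(3))
        )
        m0 = gs.penalty_nga(gs.candidate_contacts(l_object), config)
        m1 = gs.penalty_nga(gs.candidate_contacts(rotated), config)
        assert not np.allclose(m0.values, m1.values, atol=1e-6)


class TestMapIO:
    def test_tsv_roundtrip(self, tmp_path, l_maps):
        m = l_maps[2]
        path = tmp_path / "map.tsv"
        save_map(m, path)
        loaded = load_map(path)
        np.testing.assert_allclose(loaded.values, m.values, atol=1e-9)
        np.testing.assert_array_equal(loaded.mask, m.mask)
        assert loaded.label == m.label and loaded.normalized == m.normalized
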