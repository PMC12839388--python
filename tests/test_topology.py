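import numpy as np
import pytest

from _oracles import cech_persistence
from nanofoci import (
    Barcode,
    PersistenceInterval,
    SceneParams,
    alpha_persistence,
    first_generation_heatmap,
    generate_scene,
    jaccard_barcodes,
    second_generation_heatmap,
)
from nanofoci.topology import cross_heatmap


def _bars(intervals, dim=0, n_points=None, alpha_max=500.0):
    ints = [PersistenceInterval(dim, b, d) for b, d in intervals]
    return Barcode(ints, n_points or len(ints), alpha_max)


class TestAlphaPersistence:
    def test_isolated_points_components_only(self):
        pts = np.array([[0.0, 0.0], [5000.0, 0.0], [0.0, 5000.0]])
        bc = alpha_persistence(pts, alpha_max_nm=500.0)
        d0 = bc.of_dimension(0)
        assert len(d0) == 3
        assert (d0[:, 1] == 500.0).all()  # never merge below alpha_max
        assert len(bc.of_dimension(1)) == 0

    def test_two_points_merge_at_half_distance(self):
        bc = alpha_persistence(np.array([[0.0, 0.0], [120.0, 0.0]]), 500.0)
        d0 = bc.of_dimension(0)
        deaths = sorted(d0[:, 1])
        assert deaths[0] == pytest.approx(60.0)
        assert deaths[1] == 500.0

    def test_circle_has_one_hole_dying_at_radius(self):
        r = 200.0
        theta = np.linspace(0, 2 * np.pi, 20, endpoint=False)
        pts = r * np.column_stack([np.cos(theta), np.sin(theta)])
        bc = alpha_persistence(pts, 500.0)
        d1 = bc.of_dimension(1)
        assert len(d1) == 1
        assert d1[0, 1] == pytest.approx(r, abs=1e-6)
        assert len(bc.of_dimension(0)) == 20

    def test_dim0_bar_count_equals_point_count(self, rng):
        for n in (1, 2, 5, 40):
            pts = rng.random((n, 2)) * 1000
            bc = alpha_persistence(pts, 500.0)
            assert len(bc.of_dimension(0)) == n

    @pytest.mark.parametrize("seed", range(15))
    def test_cech_oracle_equivalence_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        pts = rng.random((n, 2)) * 400
        bc = alpha_persistence(pts, alpha_max_nm=500.0)
        got = sorted(
            (i.dimension, i.birth_nm, i.death_nm) for i in bc.intervals
        )
        expected = sorted(cech_persistence(pts, 500.0))
        assert len(got) == len(expected)
        for (d0, b0, dd0), (d1, b1, dd1) in zip(got, expected):
            assert d0 == d1
            assert b0 == pytest.approx(b1, abs=1e-9)
            assert dd0 == pytest.approx(dd1, abs=1e-9)

    def test_duplicate_points_handled(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [100.0, 0.0]])
        bc = alpha_persistence(pts, 500.0)
        assert len(bc.of_dimension(0)) == 3

    def test_collinear_fallback(self):
        pts = np.column_stack([np.linspace(0, 1000, 8), np.zeros(8)])
        bc = alpha_persistence(pts, 500.0)
        d0 = bc.of_dimension(0)
        assert len(d0) == 8
        assert len(bc.of_dimension(1)) == 0

    def test_errors(self):
        with pytest.raises(ValueError):
            alpha_persistence(np.zeros((0, 2)))
        with pytest.raises(ValueError):
            alpha_persistence(np.array([[0.0, 0.0]]), alpha_max_nm=-1.0)

    def test_single_and_two_points_no_holes(self):
        assert len(alpha_persistence(np.array([[1.0, 2.0]])).of_dimension(1)) == 0
        assert len(
            alpha_persistence(np.array([[0.0, 0.0], [50.0, 0.0]])).of_dimension(1)
        ) == 0


class TestJaccardBarcodes:
    def test_identity_is_one(self, rng):
        pts = rng.random((30, 2)) * 600
        bc = alpha_persistence(pts, 500.0)
        assert jaccard_barcodes(bc, bc, 0) == pytest.approx(1.0)
        assert jaccard_barcodes(bc, bc, 1) == pytest.approx(1.0)

    def test_disjoint_is_zero(self):
        b1 = _bars([(0.0, 10.0), (5.0, 8.0)], dim=1)
        b2 = _bars([(100.0, 200.0), (150.0, 300.0)], dim=1)
        assert jaccard_barcodes(b1, b2, 1) == 0.0

    def test_hand_computed_third(self):
        b1 = _bars([(0.0, 2.0)], dim=1)
        b2 = _bars([(1.0, 3.0)], dim=1)
        assert jaccard_barcodes(b1, b2, 1) == pytest.approx(1.0 / 3.0)

    def test_both_empty_one_empty(self):
        empty = _bars([], dim=1)
        full = _bars([(0.0, 5.0)], dim=1)
        assert jaccard_barcodes(empty, _bars([], dim=1), 1) == 1.0
        assert jaccard_barcodes(empty, full, 1) == 0.0
        assert jaccard_barcodes(full, empty, 1) == 0.0

    def test_symmetric_and_bounded(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(1, 8, 2)
            mk = lambda n: _bars(
                [sorted(rng.random(2) * 500) for _ in range(n)], dim=1
            )
            b1, b2 = mk(n1), mk(n2)
            s12 = jaccard_barcodes(b1, b2, 1)
            s21 = jaccard_barcodes(b2, b1, 1)
            assert s12 == pytest.approx(s21, abs=1e-12)
            assert 0.0 <= s12 <= 1.0

    def test_normalization_by_larger_count(self):
        b1 = _bars([(0.0, 10.0)], dim=1)
        b2 = _bars([(0.0, 10.0), (100.0, 200.0)], dim=1)
        assert jaccard_barcodes(b1, b2, 1) == pytest.approx(0.5)

    def test_alpha_max_mismatch_rejected(self):
        b1 = _bars([(0.0, 10.0)], alpha_max=500.0)
        b2 = _bars([(0.0, 10.0)], alpha_max=400.0)
        with pytest.raises(ValueError):
            jaccard_barcodes(b1, b2)


class TestHeatmaps:
    def test_identical_barcodes_all_ones(self):
        b = _bars([(0.0, 10.0), (0.0, 20.0)])
        hm = first_generation_heatmap([b, b], 0)
        np.testing.assert_allclose(hm.values, 1.0)

    def test_shape_symmetry_diagonal(self, rng):
        bars = [
            alpha_persistence(rng.random((10, 2)) * 300, 500.0) for _ in range(4)
        ]
        hm = first_generation_heatmap(bars, 0)
        assert hm.values.shape == (4, 4)
        np.testing.assert_allclose(hm.values, hm.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(hm.values), 1.0, atol=1e-12)
        assert ((hm.values >= 0) & (hm.values <= 1)).all()

    def test_gen1_matches_hand_computed(self):
        b1 = _bars([(0.0, 2.0)], dim=0)
        b2 = _bars([(1.0, 3.0)], dim=0)
        b3 = _bars([(0.0, 2.0)], dim=0)
        hm = first_generation_heatmap([b1, b2, b3], 0)
        assert hm.values[0, 1] == pytest.approx(1.0 / 3.0)
        assert hm.values[0, 2] == pytest.approx(1.0)
        assert hm.values[1, 2] == pytest.approx(1.0 / 3.0)

    def test_gen2_constant_maps(self):
        from nanofoci import SimilarityHeatmap

        const = SimilarityHeatmap(1, ["a", "b"], ["a", "b"],
                                  np.array([[1.0, 0.4], [0.4, 1.0]]), "components")
        gen2 = second_generation_heatmap(
            {("X", "X"): const, ("Y", "Y"): const, ("X", "Y"): const}, ["X", "Y"]
        )
        # same-label cells: mean off-diagonal = 0.4; cross-label: full mean = 0.7
        assert gen2.values[0, 0] == pytest.approx(0.4)
        assert gen2.values[1, 1] == pytest.approx(0.4)
        assert gen2.values[0, 1] == pytest.approx(0.7)
        np.testing.assert_allclose(gen2.values, gen2.values.T)

    def test_gen2_offdiag_mean_example(self):
        from nanofoci import SimilarityHeatmap

        m = SimilarityHeatmap(
            1, ["a", "b"], ["a", "b"], np.array([[1.0, 0.2], [0.4, 1.0]]), "components"
        )
        gen2 = second_generation_heatmap({("X", "X"): m}, ["X"])
        assert gen2.values[0, 0] == pytest.approx(0.3)

    def test_gen2_missing_pair_nan(self):
        from nanofoci import SimilarityHeatmap

        m = SimilarityHeatmap(1, ["a", "b"], ["a", "b"], np.eye(2), "components")
        gen2 = second_generation_heatmap({("X", "X"): m}, ["X", "Y"])
        assert np.isnan(gen2.values[0, 1]) and np.isnan(gen2.values[1, 1])

    def test_cross_heatmap_rectangular(self, rng):
        bars_a = [alpha_persistence(rng.random((8, 2)) * 300, 500.0) for _ in range(3)]
        bars_b = [alpha_persistence(rng.random((8, 2)) * 300, 500.0) for _ in range(2)]
        hm = cross_heatmap(bars_a, bars_b, 0)
        assert hm.values.shape == (3, 2)


class TestCohortProperty:
    def test_component_similarity_geq_hole_similarity(self):
        # cohort-level: mean component similarity exceeds mean hole similarity
        comp, hole = [], []
        bars = []
        for seed in range(12):
            scene = generate_scene(
                SceneParams(seed=seed, nucleus_radius_nm=1200.0, n_foci=1,
                            events_per_focus_ch1=120, background_density_ch1=30.0)
            )
            bars.append(alpha_persistence(scene.positions_ch1, 500.0))
        for i in range(len(bars)):
            for j in range(i + 1, len(bars)):
                comp.append(jaccard_barcodes(bars[i], bars[j], 0))
                hole.append(jaccard_barcodes(bars[i], bars[j], 1))
        assert np.mean(comp) > np.mean(hole)
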