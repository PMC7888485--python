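"""Thresholding tests: retention rules, consistency ratio, masked ICC,
sweep structure."""

import numpy as np
import pytest

from connrel.connectome import ConnectivityMatrix, EdgePanel, edge_index, unvectorize_upper
from connrel.reliability import edgewise_icc, icc_c1
from connrel.thresholding import (
    absolute_retention_mask,
    consistency_ratio,
    default_threshold_grid,
    relative_retention_mask,
    threshold_absolute,
    threshold_relative,
    threshold_sweep,
    thresholded_icc,
)


def matrix_from_edges(edges, r):
    return ConnectivityMatrix(
        values=unvectorize_upper(np.asarray(edges, dtype=float), r, diagonal=1.0),
        region_names=[f"R{i:03d}" for i in range(r)],
    )


def panel_pair(v1, v2, r):
    eidx = edge_index(r)
    ids = [f"s{i}" for i in range(v1.shape[0])]
    return EdgePanel(v1, eidx, ids), EdgePanel(v2, eidx.copy(), list(ids))


class TestAbsoluteThreshold:
    def test_signed_rule_zeroes_below_cutoff(self):
        m = matrix_from_edges([0.9, 0.31, 0.29, -0.5, 0.30, 0.0], 4)
        out = threshold_absolute(m, 0.30)
        kept = out.values[np.triu_indices(4, 1)]
        np.testing.assert_allclose(kept, [0.9, 0.31, 0.0, 0.0, 0.30, 0.0])
        np.testing.assert_array_equal(np.diag(out.values), np.ones(4))

    def test_unit_threshold_keeps_only_exact_ones(self):
        m = matrix_from_edges([1.0, 0.999, 0.5], 3)
        out = threshold_absolute(m, 1.0)
        np.testing.assert_allclose(
            out.values[np.triu_indices(3, 1)], [1.0, 0.0, 0.0]
        )

    def test_retained_set_matches_elementwise_rule(self, rng):
        edges = rng.uniform(-1, 1, size=45)
        m = matrix_from_edges(edges, 10)
        t = 0.2
        out = threshold_absolute(m, t)
        kept = out.values[np.triu_indices(10, 1)] != 0
        np.testing.assert_array_equal(kept, edges >= t)

    def test_invalid_threshold_rejected(self):
        m = matrix_from_edges([0.5, 0.5, 0.5], 3)
        for t in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                threshold_absolute(m, t)


class TestRelativeThreshold:
    def test_top_half_of_six_edges(self):
        m = matrix_from_edges([0.9, 0.8, 0.7, 0.3, 0.2, 0.1], 4)
        out = threshold_relative(m, 0.5)
        np.testing.assert_allclose(
            out.values[np.triu_indices(4, 1)], [0.9, 0.8, 0.7, 0, 0, 0]
        )

    def test_full_proportion_is_identity(self, rng):
        edges = rng.uniform(-1, 1, size=45)
        m = matrix_from_edges(edges, 10)
        out = threshold_relative(m, 1.0)
        np.testing.assert_array_equal(out.values, m.values)

    @pytest.mark.parametrize("p", [0.05, 0.3, 0.62, 0.99])
    def test_retained_count_is_ceil(self, rng, p):
        from math import ceil

        for _ in range(20):
            edges = rng.normal(size=45)
            mask = relative_retention_mask(edges[None, :], p)[0]
            assert mask.sum() == ceil(p * 45)
            # sort-and-count oracle: retained edges are the k largest
            k = ceil(p * 45)
            top = np.sort(edges)[::-1][:k]
            np.testing.assert_allclose(np.sort(edges[mask])[::-1], top)

    def test_ties_broken_by_canonical_order(self):
        edges = np.array([0.5, 0.5, 0.5, 0.5, 0.5, 0.5])
        mask = relative_retention_mask(edges[None, :], 0.5)[0]
        np.testing.assert_array_equal(mask, [1, 1, 1, 0, 0, 0])

    def test_nested_retention_across_thresholds(self, rng):
        values = rng.normal(size=(6, 28))
        for mask_fn, grid in (
            (relative_retention_mask, [0.2, 0.5, 0.9]),
            (absolute_retention_mask, [0.8, 0.3, 0.05]),
        ):
            masks = [mask_fn(values, t) for t in grid]
            for strict, loose in zip(masks, masks[1:]):
                assert np.all(loose[strict])  # strict set within loose set


class TestConsistencyRatio:
    def test_always_both_sessions(self):
        m = np.ones((5, 3), dtype=bool)
        np.testing.assert_allclose(consistency_ratio(m, m), 1.0)

    def test_three_subject_half_ratio(self):
        m1 = np.array([[True], [True], [False]])
        m2 = np.array([[True], [False], [False]])
        assert consistency_ratio(m1, m2)[0] == pytest.approx(0.5)

    def test_never_retained_edge_excluded(self):
        m = np.zeros((4, 2), dtype=bool)
        out = consistency_ratio(m, m)
        assert np.isnan(out).all()

    def test_matches_bruteforce_tabulation(self, rng):
        m1 = rng.random((30, 40)) < 0.5
        m2 = rng.random((30, 40)) < 0.5
        out = consistency_ratio(m1, m2)
        for e in range(40):
            both = sum(m1[s, e] and m2[s, e] for s in range(30))
            once = sum(m1[s, e] or m2[s, e] for s in range(30))
            expected = both / once if once else np.nan
            if np.isnan(expected):
                assert np.isnan(out[e])
            else:
                assert out[e] == pytest.approx(expected)
        assert np.all((out[np.isfinite(out)] >= 0) & (out[np.isfinite(out)] <= 1))


class TestThresholdedICC:
    def test_full_retention_equals_edgewise(self, rng):
        v1 = rng.normal(size=(15, 10))
        v2 = v1 + 0.3 * rng.normal(size=(15, 10))
        p1, p2 = panel_pair(v1, v2, 5)
        full = np.ones_like(v1, dtype=bool)
        masked = thresholded_icc(p1, p2, full, full, min_subjects=3)
        plain = edgewise_icc(p1, p2)
        np.testing.assert_allclose(masked.icc, plain.icc, atol=1e-12)

    def test_subject_floor_masks_sparse_edges(self, rng):
        v1 = rng.normal(size=(200, 1))
        v2 = rng.normal(size=(200, 1))
        p1, p2 = panel_pair(v1, v2, 2)
        m = np.zeros((200, 1), dtype=bool)
        m[:4] = True
        out = thresholded_icc(p1, p2, m, m, min_subjects=10)
        assert np.isnan(out.icc[0])

    def test_manual_subset_equality(self, rng):
        v1 = rng.normal(size=(30, 1))
        v2 = v1 + 0.5 * rng.normal(size=(30, 1))
        p1, p2 = panel_pair(v1, v2, 2)
        keep = np.zeros((30, 1), dtype=bool)
        chosen = [2, 5, 7, 11, 13, 17, 19, 23, 25, 29]
        keep[chosen] = True
        out = thresholded_icc(p1, p2, keep, keep, min_subjects=10)
        ref = icc_c1(np.column_stack([v1[chosen, 0], v2[chosen, 0]]))
        assert out.icc[0] == pytest.approx(ref.icc, abs=1e-12)
        assert out.n[0] == 10


class TestThresholdSweep:
    def test_grid_shape_and_limits(self):
        grid = default_threshold_grid()
        assert grid.shape == (20,)
        assert grid[0] == pytest.approx(0.05)
        assert grid[-1] == pytest.approx(1.0)
        assert np.all(np.diff(grid) > 0)

    def test_duplicate_sessions_are_perfectly_consistent(self, rng):
        v = rng.uniform(-0.3, 0.9, size=(12, 45))
        p1, p2 = panel_pair(v, v.copy(), 10)
        report = threshold_sweep(p1, p2, mode="relative", min_subjects=3)
        np.testing.assert_allclose(report.consistency_median, 1.0)
        assert np.isnan(report.trend_consistency_rho)  # constant medians

    def test_report_regenerates_identically(self, rng):
        v1 = rng.normal(0.2, 0.2, size=(15, 45))
        v2 = v1 + rng.normal(0, 0.1, size=(15, 45))
        p1, p2 = panel_pair(v1, v2, 10)
        import json

        a = threshold_sweep(p1, p2, mode="absolute", min_subjects=3).to_dict()
        b = threshold_sweep(p1, p2, mode="absolute", min_subjects=3).to_dict()
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)

    def test_invalid_inputs_rejected(self, rng):
        v = rng.normal(size=(5, 3))
        p1, p2 = panel_pair(v, v, 3)
        with pytest.raises(ValueError):
            threshold_sweep(p1, p2, mode="weird")
        with pytest.raises(ValueError):
            threshold_sweep(p1, p2, thresholds=np.array([0.5, 0.4]))
        with pytest.raises(ValueError):
            threshold_sweep(p1, p2, thresholds=np.array([0.0, 0.5]))

    def test_relative_mode_consistency_falls_with_stringency(self, panels100):
        """Study-scale check: the median consistency ratio declines
        monotonically as the retained proportion shrinks."""
        p1, p2 = panels100[False]
        report = threshold_sweep(p1, p2, mode="relative")
        med = report.consistency_median
        # medians rise with the retained proportion (ties allowed at the top)
        assert np.all(np.diff(med) >= 0)
        assert report.trend_consistency_rho < -0.95

    def test_absolute_mode_declines_sharply(self, panels100):
        p1, p2 = panels100[False]
        report = threshold_sweep(p1, p2, mode="absolute")
        med = report.consistency_median
        ok = np.isfinite(med)
        assert med[ok][0] > 0.5
        assert np.all(np.diff(med[ok]) <= 1e-12)
        assert report.trend_consistency_rho < -0.9
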