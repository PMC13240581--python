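"""Dose accumulation and DVH engine against brute-force voxel oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from igsched import (
    DoseGrid,
    GeometryError,
    StructureMask,
    accumulate,
    compute_dvh,
    deliver_fraction,
    dvh_metric,
)

BW = 0.05


def grid_from(values, spacing=4.0):
    return DoseGrid(np.asarray(values, dtype=float), spacing=spacing)


def full_mask(shape, spacing=4.0):
    return StructureMask("roi", np.ones(shape, bool), spacing=spacing)


class TestAccumulate:
    def test_partition_of_unity(self, tiny_phantom):
        planned, _ = tiny_phantom
        parts = [planned.with_values(planned.values / 25)] * 25
        total = accumulate(parts)
        np.testing.assert_allclose(total.values, planned.values, rtol=1e-6)

    def test_single_grid_identity(self, tiny_phantom):
        planned, _ = tiny_phantom
        np.testing.assert_array_equal(accumulate([planned]).values, planned.values)

    def test_order_invariance(self, rng):
        grids = [grid_from(rng.random((6, 6, 6))) for _ in range(5)]
        a = accumulate(grids).values
        b = accumulate(grids[::-1]).values
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_geometry_mismatch_rejected(self, rng):
        a = grid_from(rng.random((6, 6, 6)), spacing=4.0)
        b = grid_from(rng.random((6, 6, 6)), spacing=2.0)
        with pytest.raises(GeometryError):
            accumulate([a, b])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            accumulate([])


class TestComputeDvh:
    def test_uniform_dose_is_step_function(self):
        g = grid_from(np.full((4, 4, 4), 50.0))
        dvh = compute_dvh(g, full_mask(g.shape))
        mids, vols = dvh.differential()
        # all volume in the single bin containing 50 Gy
        assert vols[np.abs(mids - 50.0) <= BW].sum() == pytest.approx(1.0)
        assert dvh.cum_volume[0] == 1.0
        assert dvh.cum_volume[-1] == 0.0

    def test_two_level_dose_cumulative_half(self):
        values = np.concatenate([np.full(32, 10.0), np.full(32, 30.0)]).reshape(4, 4, 4)
        dvh = compute_dvh(grid_from(values), full_mask((4, 4, 4)))
        inside = (dvh.edges > 10.0 + BW) & (dvh.edges <= 30.0)
        assert np.all(dvh.cum_volume[inside] == pytest.approx(0.5))

    def test_monotone_nonincreasing(self, rng):
        g = grid_from(rng.random((8, 8, 8)) * 60)
        dvh = compute_dvh(g, full_mask(g.shape))
        assert np.all(np.diff(dvh.cum_volume) <= 0)

    def test_matches_sorted_voxel_curve(self, rng):
        g = grid_from(rng.random((8, 8, 8)) * 60)
        dvh = compute_dvh(g, full_mask(g.shape))
        vox = np.sort(g.values.ravel())
        for edge, cum in zip(dvh.edges, dvh.cum_volume):
            brute = np.mean(vox >= edge)
            assert cum == pytest.approx(brute, abs=1e-12)

    def test_geometry_mismatch_and_structure_name_in_error(self, rng):
        g = grid_from(rng.random((6, 6, 6)))
        with pytest.raises(GeometryError):
            compute_dvh(g, full_mask((5, 5, 5)))


class TestMetrics:
    def test_uniform_dose_all_metrics(self):
        g = grid_from(np.full((4, 4, 4), 50.0))
        dvh = compute_dvh(g, full_mask(g.shape))
        for metric in ("D95", "Dmean", "Dmax"):
            assert dvh_metric(dvh, metric) == pytest.approx(50.0, abs=BW + 1e-9)

    def test_hand_computed_percentile_and_mean(self):
        # 100 voxels: 95 at 50 Gy, 5 at 10 Gy -> D95 = 50, Dmean = 48
        values = np.concatenate([np.full(95, 50.0), np.full(5, 10.0), [0.0] * 25])
        mask = np.zeros(125, bool)
        mask[:100] = True
        g = grid_from(values.reshape(5, 5, 5))
        dvh = compute_dvh(g, StructureMask("roi", mask.reshape(5, 5, 5)))
        assert dvh_metric(dvh, "D95") == pytest.approx(50.0, abs=BW)
        assert dvh_metric(dvh, "Dmean") == pytest.approx(48.0, abs=BW / 2)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_d95_and_dmean_match_voxel_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = grid_from(rng.random((6, 6, 6)) * rng.uniform(5, 80))
        dvh = compute_dvh(g, full_mask(g.shape))
        vox = np.sort(g.values.ravel())
        # brute-force D95: largest dose received by >= 95% of voxels
        n = vox.size
        oracle = vox[n - int(np.ceil(0.95 * n))]
        assert dvh_metric(dvh, "D95") == pytest.approx(oracle, abs=BW)
        assert dvh_metric(dvh, "Dmean") == pytest.approx(vox.mean(), abs=BW / 2)
        assert dvh_metric(dvh, "Dmax") == pytest.approx(vox.max(), abs=BW)

    def test_bin_refinement_stability(self, rng):
        g = grid_from(rng.random((8, 8, 8)) * 60)
        coarse = compute_dvh(g, full_mask(g.shape), bin_width=0.05)
        fine = compute_dvh(g, full_mask(g.shape), bin_width=0.01)
        for metric in ("D95", "Dmean", "Dmax"):
            assert dvh_metric(coarse, metric) == pytest.approx(
                dvh_metric(fine, metric), abs=0.05
            )

    def test_unknown_metric_rejected(self, rng):
        g = grid_from(rng.random((4, 4, 4)))
        dvh = compute_dvh(g, full_mask(g.shape))
        with pytest.raises(ValueError, match="unknown"):
            dvh_metric(dvh, "V20")


class TestCompositionConsistency:
    def test_uniform_shift_accumulation_equals_single_shifted_course(self, tiny_phantom):
        # 25 fractions at one common shift must reproduce the DVH of the
        # whole shifted course
        planned, masks = tiny_phantom
        shift = (5.0, -3.0, 2.0)
        fractions = [deliver_fraction(planned, shift, 25) for _ in range(25)]
        acc = accumulate(fractions)
        course = deliver_fraction(planned, shift, 1)
        a = compute_dvh(acc, masks["PTVcw"])
        b = compute_dvh(course, masks["PTVcw"])
        for metric in ("D95", "Dmean", "Dmax"):
            assert dvh_metric(a, metric) == pytest.approx(
                dvh_metric(b, metric), abs=BW
            )
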