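"""Mask binarization, tissue summaries, group averaging, recovery scoring."""

import numpy as np
import pytest

import cvrlag as cl
from cvrlag.errors import EmptyRegionError, InvalidSpecError


def vmap(data, valid=None, units="seconds"):
    data = np.asarray(data, float)
    if valid is None:
        valid = np.isfinite(data)
    return cl.VoxelMap(data, units, valid)


class TestBinarizeMask:
    def test_inclusive_boundary(self):
        prob = np.full((2, 2, 1), 0.50)
        assert cl.binarize_mask(prob, 50.0).all()

    def test_gm_wm_thresholds_on_intermediate_probability(self):
        prob = np.full((2, 2, 1), 0.6)
        assert cl.binarize_mask(prob, 50.0).all()      # GM mask full
        assert not cl.binarize_mask(prob, 90.0).any()  # WM mask empty

    def test_full_threshold_keeps_only_certain_voxels(self):
        prob = np.zeros((2, 2, 1))
        prob[0, 0, 0] = 1.0
        mask = cl.binarize_mask(prob, 100.0)
        assert mask.sum() == 1 and mask[0, 0, 0]

    @pytest.mark.parametrize("thr", [0.0, -5.0, 101.0])
    def test_threshold_bounds(self, thr):
        with pytest.raises(InvalidSpecError):
            cl.binarize_mask(np.full((1, 1, 1), 0.5), thr)

    def test_phantom_masks_disjoint_at_paper_thresholds(self):
        truth = cl.draw_truth(cl.PhantomSpec(seed=0))
        gm = cl.binarize_mask(truth.gm_prob, 50.0)
        wm = cl.binarize_mask(truth.wm_prob, 90.0)
        assert not (gm & wm).any()


class TestTissueSummary:
    def test_mean_and_sample_sd(self):
        m = vmap(np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1))
        s = cl.tissue_summary(m, np.ones((3, 1, 1), bool), bins=np.arange(0, 5.0))
        assert s.mean == pytest.approx(2.0)
        assert s.sd == pytest.approx(1.0)
        assert s.n_voxels == 3

    def test_single_bin_jump(self):
        m = vmap(np.full((4, 1, 1), 2.5))
        s = cl.tissue_summary(m, np.ones((4, 1, 1), bool),
                              bins=np.array([0.0, 1, 2, 3, 4]))
        assert np.allclose(s.cumulative_pct, [0, 0, 100, 100])

    def test_uniform_values_against_counting_oracle(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 40, size=1000)
        m = vmap(vals.reshape(10, 10, 10))
        bins = np.arange(0.0, 44.0, 4.0)
        s = cl.tissue_summary(m, np.ones((10, 10, 10), bool), bins=bins)
        counts = np.array([(vals < e).sum() for e in bins[1:]])
        assert np.allclose(s.cumulative_pct, 100.0 * counts / len(vals), atol=1e-9)

    def test_mass_conservation_and_endpoint(self):
        rng = np.random.default_rng(8)
        m = vmap(rng.normal(10, 30, size=(6, 6, 2)))
        s = cl.tissue_summary(m, np.ones((6, 6, 2), bool))
        assert s.cumulative_pct[-1] == pytest.approx(100.0, abs=1e-9)
        assert s.bin_pct.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.all(np.diff(s.cumulative_pct) >= -1e-12)

    def test_empty_region_rejected(self):
        m = vmap(np.ones((2, 2, 1)), valid=np.zeros((2, 2, 1), bool))
        with pytest.raises(EmptyRegionError):
            cl.tissue_summary(m, np.ones((2, 2, 1), bool))


class TestGroupAverage:
    def _stack(self, values, valid_counts, shape=(2, 2, 1)):
        maps = []
        for i, v in enumerate(values):
            data = np.full(shape, float(v))
            valid = np.ones(shape, bool) if i < valid_counts else np.zeros(shape, bool)
            maps.append(cl.VoxelMap(data, "seconds", valid))
        return maps

    def test_minimum_coverage_filter(self):
        maps = self._stack(range(9), valid_counts=3)
        out = cl.group_average(maps, min_points=4)
        assert out.valid.sum() == 0

    def test_identical_fully_valid_maps(self):
        maps = self._stack([7.0] * 5, valid_counts=5)
        out = cl.group_average(maps)
        assert np.allclose(out.data, 7.0)
        assert out.valid.all()

    def test_mean_of_survivors_matches_direct_recomputation(self):
        rng = np.random.default_rng(0)
        shape = (1, 1, 1)
        values = np.arange(1.0, 10.0)
        drop = set(rng.choice(9, size=4, replace=False).tolist())
        maps = []
        for i, v in enumerate(values):
            valid = np.full(shape, i not in drop)
            maps.append(cl.VoxelMap(np.full(shape, v), "seconds", valid))
        out = cl.group_average(maps)
        survivors = [v for i, v in enumerate(values) if i not in drop]
        assert out.data[0, 0, 0] == pytest.approx(np.mean(survivors))
        # and the full stack averages to 5
        full = cl.group_average(self._stack(values, valid_counts=9, shape=shape))
        assert full.data[0, 0, 0] == pytest.approx(5.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        maps = [cl.VoxelMap(rng.normal(size=(3, 3, 2)), "seconds",
                            rng.random((3, 3, 2)) > 0.3) for _ in range(6)]
        a = cl.group_average(maps, min_points=2)
        b = cl.group_average(maps[::-1], min_points=2)
        assert np.array_equal(a.valid, b.valid)
        assert np.allclose(a.data[a.valid], b.data[b.valid])

    def test_empty_list_rejected(self):
        with pytest.raises(InvalidSpecError):
            cl.group_average([])


class TestRecoveryReport:
    def _truth(self):
        return cl.draw_truth(cl.PhantomSpec(grid_shape=(8, 8, 1), seed=2))

    def test_perfect_estimate_scores_zero(self):
        truth = self._truth()
        est = {"lag": truth.true_lag, "cvr": truth.true_cvr}
        masks = {"GM": truth.gm_mask, "WM": truth.wm_mask}
        rep = cl.recovery_report(est, truth, masks)
        for entry in rep.entries.values():
            assert entry["bias"] == pytest.approx(0.0, abs=1e-12)
            assert entry["rmse"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_appears_as_bias_and_rmse(self):
        truth = self._truth()
        shifted = cl.VoxelMap(truth.true_lag.data + 1.0, "seconds",
                              truth.true_lag.valid)
        rep = cl.recovery_report({"lag": shifted}, truth,
                                 {"GM": truth.gm_mask})
        e = rep.entries["GM.lag"]
        assert e["bias"] == pytest.approx(1.0)
        assert e["rmse"] == pytest.approx(1.0)
        assert e["rmse"] >= abs(e["bias"])

    def test_grid_mismatch_rejected(self):
        truth = self._truth()
        other = cl.VoxelMap(np.zeros((4, 4, 1)), "seconds", np.ones((4, 4, 1), bool))
        with pytest.raises(InvalidSpecError):
            cl.recovery_report({"lag": other}, truth, {"GM": truth.gm_mask})
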