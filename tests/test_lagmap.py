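"""Cross-correlation lag search and optimized-regressor refinement."""

import numpy as np
import pytest
from scipy.interpolate import CubicSpline

import cvrlag as cl
from cvrlag.errors import EmptyRegionError, InvalidSpecError, RefinementError
from cvrlag.lagmap import Regressor

DT = 0.375  # 8x oversampled 3 s TR


def probe_regressor(n=800, seed=0):
    """A z-scored boxcar-like reference on the fine grid."""
    t = np.arange(n) * DT
    v = ((t >= 100) & (t < 190)).astype(float) * 8.0
    v += 0.01 * np.sin(t / 17.0)  # break flatness so shifts are identifiable
    return Regressor.from_series(v, DT)


def brute_force_lag(vox, reg, dt, lag_min, lag_max, min_frac=0.25):
    """Direct-sum oracle: all candidate lags, Pearson r via np.corrcoef."""
    N, M = len(vox), len(reg)
    best = (-np.inf, None)
    m_lo = int(np.ceil(lag_min / dt - 1e-9))
    m_hi = int(np.floor(lag_max / dt + 1e-9))
    cands = [m for m in range(m_lo, m_hi + 1)
             if min(N, m + M) - max(0, m) >= max(3, int(np.ceil(min_frac * min(N, M))))]
    for m in sorted(cands, key=lambda m: (abs(m * dt), m * dt)):
        a, b = max(0, m), min(N, m + M)
        v, r_ = vox[a:b], reg[a - m: b - m]
        if v.std() == 0 or r_.std() == 0:
            continue
        r = np.corrcoef(v, r_)[0, 1]
        if r > best[0]:
            best = (r, m * dt)
    return best[1], best[0]


class TestXcorrLag:
    def test_identity_gives_zero_lag_unit_r(self):
        reg = probe_regressor()
        vox = cl.UniformTrace(reg.trace.values.copy(), DT)
        res = cl.xcorr_lag(vox, reg)
        assert res.lag_s == 0.0
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_pure_shift_of_twelve_steps(self):
        reg = probe_regressor()
        v = reg.trace.values
        vox = cl.UniformTrace(np.concatenate([np.full(12, v[0]), v[:-12]]), DT)
        res = cl.xcorr_lag(vox, reg)
        assert res.lag_s == pytest.approx(4.5)
        assert res.r > 0.999

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vox = rng.normal(size=80)
        reg_vals = rng.normal(size=80)
        reg = Regressor.from_series(reg_vals, DT)
        res = cl.xcorr_lag(cl.UniformTrace(vox, DT), reg,
                           cl.LagAnalysisConfig(lag_min_s=-10, lag_max_s=10))
        lag_o, r_o = brute_force_lag(vox, reg.trace.values, DT, -10, 10)
        assert res.lag_s == pytest.approx(lag_o, abs=1e-12)
        assert res.r == pytest.approx(r_o, abs=1e-10)

    def test_degenerate_voxel_flagged_not_raised(self):
        reg = probe_regressor()
        res = cl.xcorr_lag(cl.UniformTrace(np.full(800, 7.0), DT), reg)
        assert res.degenerate
        assert np.isnan(res.lag_s) and np.isnan(res.r)

    def test_r_invariant_to_affine_voxel_rescaling(self):
        reg = probe_regressor()
        rng = np.random.default_rng(9)
        vox = rng.normal(size=800)
        r1 = cl.xcorr_lag(cl.UniformTrace(vox, DT), reg)
        r2 = cl.xcorr_lag(cl.UniformTrace(5.0 * vox + 300.0, DT), reg)
        assert r1.lag_s == r2.lag_s
        assert r1.r == pytest.approx(r2.r, abs=1e-12)

    def test_shift_equivariance(self):
        # delaying every voxel by d shifts every lag by d (within one step)
        reg = probe_regressor()
        v = reg.trace.values
        d_steps = 10
        rng = np.random.default_rng(2)
        for true_steps in (8, 40, 100):
            vox = np.roll(v, true_steps) + 0.01 * rng.normal(size=v.size)
            base = cl.xcorr_lag(cl.UniformTrace(vox, DT), reg)
            delayed = cl.xcorr_lag(
                cl.UniformTrace(np.roll(vox, d_steps), DT), reg)
            assert delayed.lag_s - base.lag_s == pytest.approx(d_steps * DT, abs=DT)

    def test_regressor_must_be_normalized(self):
        with pytest.raises(InvalidSpecError):
            Regressor(trace=cl.UniformTrace(np.arange(10.0), DT))


class TestOptimizedRegressor:
    def _bold_from_series(self, series_list, shape):
        nt = len(series_list[0])
        data = np.zeros(shape + (nt,))
        flat = data.reshape(-1, nt)
        for i, s in enumerate(series_list):
            flat[i] = s
        return cl.BoldImage4D(data, DT)

    def test_identical_voxels_reproduce_the_probe(self):
        reg = probe_regressor(n=400)
        v = reg.trace.values
        bold = self._bold_from_series([1000 + 5 * v] * 4, (2, 2, 1))
        gm = np.ones((2, 2, 1), bool)
        out = cl.build_optimized_regressor(bold, reg, gm)
        assert out.provenance == "OPTIMIZED"
        assert out.n_voxels_used == 4
        common = slice(0, len(out.trace.values))
        ref = v[common]
        ref = (ref - ref.mean()) / ref.std()
        assert np.allclose(out.trace.values, ref, atol=1e-8)

    def test_voxelwise_shifts_are_undone(self):
        reg = probe_regressor(n=600)
        v = reg.trace.values
        t = np.arange(len(v)) * DT
        spline = CubicSpline(t, v)
        lags = [0.0, 1.5, 3.0, 6.0, 7.5, 12.0]
        series = [1000 + 4 * spline(np.clip(t - L, 0, t[-1])) for L in lags]
        bold = self._bold_from_series(series, (3, 2, 1))
        gm = np.ones((3, 2, 1), bool)
        out = cl.build_optimized_regressor(bold, reg, gm)
        # realigned average must match the probe shape on the common support
        i0 = int(round(out.trace.t0_s / DT))
        ref = v[i0: i0 + len(out.trace.values)]
        r = np.corrcoef(out.trace.values, ref)[0, 1]
        assert r > 0.999

    def test_unreachable_threshold_raises(self):
        rng = np.random.default_rng(0)
        reg = probe_regressor(n=400)
        noise = [1000 + rng.normal(size=400) for _ in range(4)]
        bold = self._bold_from_series(noise, (2, 2, 1))
        gm = np.ones((2, 2, 1), bool)
        with pytest.raises(RefinementError, match="0.99"):
            cl.build_optimized_regressor(
                bold, reg, gm, cl.LagAnalysisConfig(r_threshold=0.99))


class TestLagMap:
    def test_all_background_volume_has_no_valid_voxel(self):
        reg = probe_regressor(n=400)
        bold = cl.BoldImage4D(np.full((3, 3, 1, 400), 1000.0), DT)
        lag, rmap = cl.compute_lag_map(bold, reg)
        assert lag.valid.sum() == 0
        assert np.all(np.isnan(lag.data))

    def test_empty_mask_rejected(self):
        reg = probe_regressor(n=400)
        bold = cl.BoldImage4D(np.full((3, 3, 1, 400), 1000.0), DT)
        with pytest.raises(EmptyRegionError):
            cl.compute_lag_map(bold, reg, brain_mask=np.zeros((3, 3, 1), bool))

    def test_monotone_degradation_with_noise(self, block_trace):
        # median |lag error| must not improve as tsnr falls
        medians = []
        for tsnr in (0.0, 100.0, 50.0, 20.0):
            spec = cl.PhantomSpec(grid_shape=(10, 10, 1), tsnr=tsnr, seed=6)
            truth = cl.draw_truth(cl.PhantomSpec(grid_shape=(10, 10, 1), seed=6))
            bold, _, _ = cl.simulate_bold(block_trace, spec, truth=truth)
            res = cl.analyze(bold, block_trace, truth.gm_prob, truth.wm_prob,
                             probe_only=True)
            sel = res.lag.valid
            err = np.abs(res.lag.data[sel] + res.alignment_shift_s
                         - truth.true_lag.data[sel])
            medians.append(np.median(err))
        assert all(m2 >= m1 - 1e-9 for m1, m2 in zip(medians, medians[1:]))
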