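"""Voxelwise hemodynamic lag estimation by cross-correlation.

The lag of a voxel is the time shift that maximizes the Pearson correlation
between its (denoised, oversampled) time course and a reference regressor.
The initial probe regressor is the aligned, oversampled end-tidal CO2 trace;
an optimized regressor is then built by shifting every high-correlation
gray-matter voxel back by its estimated lag, z-scoring, and averaging over the
common temporal support — a data-driven refinement in the spirit of
rapid-interpolation-at-progressive-time-delays (RIPTiDe) lag mapping.

Conventions: a positive lag means the voxel trails the regressor. Candidate
lags live on the oversampled grid (no sub-sample refinement); ties are broken
toward the smallest absolute lag; a peak at a search boundary invalidates the
voxel rather than being clamped, to avoid pile-up artifacts in lag histograms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.interpolate import CubicSpline

from .containers import BoldImage4D, UniformTrace, VoxelMap, zscore
from .errors import EmptyRegionError, InvalidSpecError, RefinementError

PROBE_PETCO2 = "PROBE_PETCO2"
OPTIMIZED = "OPTIMIZED"

#: Minimum fraction of the series that must overlap at a candidate lag.
MIN_OVERLAP_FRAC = 0.25


@dataclass
class Regressor:
    """A normalized (zero-mean, unit-SD) reference time course."""

    trace: UniformTrace
    provenance: str = PROBE_PETCO2
    n_voxels_used: int | None = None

    def __post_init__(self) -> None:
        v = self.trace.values
        if abs(v.mean()) > 1e-10 or abs(v.std() - 1) > 1e-10:
            raise InvalidSpecError("regressor must be z-scored (mean 0, SD 1)")

    @classmethod
    def from_series(cls, values: np.ndarray, dt_s: float, t0_s: float = 0.0,
                    provenance: str = PROBE_PETCO2,
                    n_voxels_used: int | None = None) -> "Regressor":
        return cls(trace=UniformTrace(values=zscore(values), dt_s=dt_s, t0_s=t0_s),
                   provenance=provenance, n_voxels_used=n_voxels_used)


@dataclass(frozen=True)
class LagAnalysisConfig:
    """Lag-search and regressor-refinement settings.

    The default search window [-10, +90] s accommodates the long white-matter
    delays seen under progressive hypercapnia (tissue means past 40 s) while
    allowing small negative lags around the alignment reference.
    """

    lag_min_s: float = -10.0
    lag_max_s: float = 90.0
    oversample_factor: int = 8
    r_threshold: float = 0.3
    refine_passes: int = 1
    gm_only_refine: bool = True

    def __post_init__(self) -> None:
        if not self.lag_min_s < self.lag_max_s:
            raise InvalidSpecError("lag_min_s must be < lag_max_s")
        if self.oversample_factor < 1:
            raise InvalidSpecError("oversample_factor must be >= 1")
        if not 0 <= self.r_threshold < 1:
            raise InvalidSpecError("r_threshold must lie in [0, 1)")
        if self.refine_passes < 0:
            raise InvalidSpecError("refine_passes must be >= 0")


class LagSearchResult(NamedTuple):
    lag_s: np.ndarray
    r: np.ndarray
    at_boundary: np.ndarray
    degenerate: np.ndarray


def _lag_search(vox: np.ndarray, reg: np.ndarray, dt_s: float, reg_t0_s: float,
                lag_min_s: float, lag_max_s: float) -> LagSearchResult:
    """Exhaustive correlation search over candidate lags for many voxels.

    ``vox`` is (n_voxels, N) on the grid t = 0, dt, ...; ``reg`` is (M,) on
    t = reg_t0 + j*dt. Candidate lag L maps voxel sample n onto regressor
    sample n - m with m = (L + reg_t0)/dt; correlations use the overlapping
    support only and require at least MIN_OVERLAP_FRAC of min(N, M) samples.
    """
    vox = np.atleast_2d(np.asarray(vox, float))
    reg = np.asarray(reg, float)
    nv, N = vox.shape
    M = len(reg)
    base = min(N, M)
    min_len = max(3, int(np.ceil(MIN_OVERLAP_FRAC * base)))

    m_lo = int(np.ceil((lag_min_s + reg_t0_s) / dt_s - 1e-9))
    m_hi = int(np.floor((lag_max_s + reg_t0_s) / dt_s + 1e-9))
    cand = [m for m in range(m_lo, m_hi + 1)
            if min(N, m + M) - max(0, m) >= min_len]
    if not cand:
        raise InvalidSpecError("no candidate lag leaves enough overlap")
    cand = np.asarray(cand)
    lags = cand * dt_s - reg_t0_s
    # tie-break toward smallest |lag| (and toward the earlier, i.e. more
    # negative, lag between exact +/- ties): scan in that order, update on
    # strictly greater correlation.
    order = np.lexsort((lags, np.abs(lags)))

    # prefix sums for O(1) per-candidate segment means/variances
    cs = np.concatenate([np.zeros((nv, 1)), np.cumsum(vox, axis=1)], axis=1)
    cs2 = np.concatenate([np.zeros((nv, 1)), np.cumsum(vox**2, axis=1)], axis=1)

    best_r = np.full(nv, -np.inf)
    best_lag = np.full(nv, np.nan)
    best_edge = np.zeros(nv, dtype=bool)
    lag_lo, lag_hi = lags.min(), lags.max()
    degenerate = vox.std(axis=1) == 0

    for idx in order:
        m = int(cand[idx])
        a, b = max(0, m), min(N, m + M)
        rs = reg[a - m: b - m]
        rsd = rs.std()
        if rsd == 0:
            continue
        rsn = (rs - rs.mean()) / rsd
        n = b - a
        seg_sum = cs[:, b] - cs[:, a]
        seg_sq = cs2[:, b] - cs2[:, a]
        var = seg_sq / n - (seg_sum / n) ** 2
        sd = np.sqrt(np.maximum(var, 0.0))
        num = vox[:, a:b] @ rsn  # rsn sums to zero, so no mean term needed
        with np.errstate(divide="ignore", invalid="ignore"):
            r = num / (sd * n)
        r[~np.isfinite(r)] = -np.inf
        np.clip(r, -1.0, 1.0, out=r)
        upd = r > best_r
        if np.any(upd):
            L = lags[idx]
            best_r[upd] = r[upd]
            best_lag[upd] = L
            best_edge[upd] = (L <= lag_lo + 1e-12) | (L >= lag_hi - 1e-12)

    ok = np.isfinite(best_r) & ~degenerate
    best_r[~ok] = np.nan
    best_lag[~ok] = np.nan
    return LagSearchResult(lag_s=best_lag, r=best_r, at_boundary=best_edge,
                           degenerate=~ok)


class LagResult(NamedTuple):
    lag_s: float
    r: float
    at_boundary: bool
    degenerate: bool


def xcorr_lag(voxel: UniformTrace, reg: Regressor,
              cfg: LagAnalysisConfig = LagAnalysisConfig()) -> LagResult:
    """Lag and peak correlation of a single voxel series against a regressor.

    A zero-variance voxel is flagged degenerate (lag and r are NaN) rather
    than raising.
    """
    if abs(voxel.dt_s - reg.trace.dt_s) > 1e-12:
        raise InvalidSpecError("voxel and regressor must share the sampling step")
    res = _lag_search(voxel.values[None, :], reg.trace.values, voxel.dt_s,
                      reg.trace.t0_s - voxel.t0_s, cfg.lag_min_s, cfg.lag_max_s)
    return LagResult(float(res.lag_s[0]), float(res.r[0]),
                     bool(res.at_boundary[0]), bool(res.degenerate[0]))


def build_optimized_regressor(bold: BoldImage4D, probe: Regressor,
                              gm_mask: np.ndarray,
                              cfg: LagAnalysisConfig = LagAnalysisConfig()) -> Regressor:
    """Refine the probe into a data-driven regressor from high-r voxels.

    Each refinement pass estimates per-voxel (lag, r) against the current
    regressor, selects voxels with r >= ``cfg.r_threshold`` (gray matter only
    when ``gm_only_refine``), undoes each voxel's lag by cubic interpolation,
    z-scores the realigned series and averages them sample-wise over their
    common support; the z-scored average becomes the next regressor.

    ``bold`` must already be denoised and oversampled to the analysis grid.
    """
    gm_mask = np.asarray(gm_mask, bool)
    if not gm_mask.any():
        raise EmptyRegionError("gray-matter mask is empty")
    sel_mask = gm_mask if cfg.gm_only_refine else np.ones(bold.grid_shape, bool)
    series = bold.data[sel_mask]
    keep = series.std(axis=1) > 0
    series = series[keep]
    if series.shape[0] == 0:
        raise RefinementError("no voxel with temporal variance in the refine mask")

    dt = bold.tr_s
    N = bold.nt
    t = np.arange(N) * dt
    reg = probe
    n_used = 0
    for _ in range(max(cfg.refine_passes, 1)):
        res = _lag_search(series, reg.trace.values, dt, reg.trace.t0_s,
                          cfg.lag_min_s, cfg.lag_max_s)
        passing = (~res.degenerate) & (~res.at_boundary) & (res.r >= cfg.r_threshold)
        n_used = int(passing.sum())
        if n_used == 0:
            raise RefinementError(
                f"no voxel reached the correlation threshold r >= {cfg.r_threshold}")
        lags = res.lag_s[passing]
        sel = series[passing]
        # common support: t + lag_v must stay inside [0, (N-1) dt] for all voxels
        i0 = max(0, int(np.ceil(-lags.min() / dt - 1e-9)))
        i1 = min(N, int(np.floor(((N - 1) * dt - lags.max()) / dt + 1e-9)) + 1)
        if i1 - i0 < 16:
            raise RefinementError("common support after lag removal is too short")
        tt = t[i0:i1]
        acc = np.zeros(i1 - i0)
        for i in range(sel.shape[0]):
            aligned = CubicSpline(t, sel[i])(tt + lags[i])
            acc += zscore(aligned)
        reg = Regressor.from_series(acc / n_used, dt_s=dt, t0_s=i0 * dt,
                                    provenance=OPTIMIZED, n_voxels_used=n_used)
    if cfg.refine_passes == 0:
        return probe
    return reg


def compute_lag_map(bold: BoldImage4D, reg: Regressor,
                    cfg: LagAnalysisConfig = LagAnalysisConfig(),
                    brain_mask: np.ndarray | None = None) -> tuple[VoxelMap, VoxelMap]:
    """Per-voxel lag (seconds) and peak correlation maps inside a brain mask.

    Voxels are invalid where degenerate (no temporal variance), where the
    correlation peak sits on a search boundary, or where the peak correlation
    falls below ``cfg.r_threshold``.
    """
    if brain_mask is None:
        brain_mask = np.ones(bold.grid_shape, bool)
    brain_mask = np.asarray(brain_mask, bool)
    if not brain_mask.any():
        raise EmptyRegionError("brain mask is empty")
    vox = bold.data[brain_mask]
    res = _lag_search(vox, reg.trace.values, bold.tr_s, reg.trace.t0_s,
                      cfg.lag_min_s, cfg.lag_max_s)
    shape = bold.grid_shape
    lag = np.full(shape, np.nan)
    rr = np.full(shape, np.nan)
    lag[brain_mask] = res.lag_s
    rr[brain_mask] = res.r
    ok = np.zeros(shape, bool)
    ok[brain_mask] = (~res.degenerate) & (~res.at_boundary) & (res.r >= cfg.r_threshold)
    return (VoxelMap(lag, "seconds", ok), VoxelMap(rr, "r", ok))
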