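"""Voxelwise cerebrovascular reactivity (CVR) regression.

CVR is the slope, in percent BOLD signal change per mmHg, of an ordinary
least-squares fit of the end-tidal CO2 trace against the voxel's percent
signal change. The percent change reference is the mean signal over a
pre-stimulus baseline window. With lag adjustment enabled, the CO2 trace is
first shifted by the voxel's estimated hemodynamic lag (linear
interpolation on the overlapping support only; the trace is piecewise linear
between breath samples, so this shift is exact), which removes the delay-induced underestimation of
CVR in late-responding tissue.

The regression runs on the TR grid — not the oversampled lag-analysis grid —
so residual degrees of freedom reflect the number of acquired volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from .containers import BoldImage4D, UniformTrace, VoxelMap
from .errors import DegenerateInputError, EmptyRegionError, InvalidSpecError


@dataclass(frozen=True)
class CvrConfig:
    """CVR regression settings.

    ``baseline_window_s`` is a (start, end) window on the pre-stimulus
    segment used as the percent-change reference. ``None`` (the default)
    derives it from the trace itself: the full pre-stimulus period minus its
    first 15 s, ending at the stimulus onset. Voxels with fewer than
    ``min_valid_points`` overlapping trace samples are invalidated.
    """

    baseline_window_s: tuple[float, float] | None = None
    use_lag_adjustment: bool = True
    min_valid_points: int = 4

    def __post_init__(self) -> None:
        if self.baseline_window_s is not None:
            lo, hi = self.baseline_window_s
            if not (0 <= lo < hi):
                raise InvalidSpecError(
                    "baseline window must satisfy 0 <= start < end")
        if self.min_valid_points < 2:
            raise InvalidSpecError("min_valid_points must be >= 2")


#: Seconds discarded at the start of the pre-baseline (settling period).
BASELINE_SKIP_S = 15.0


def baseline_window_from_trace(trace: UniformTrace,
                               skip_s: float = BASELINE_SKIP_S) -> tuple[float, float]:
    """Derive the percent-change reference window from the stimulus onset.

    The onset is the first sample departing from the initial level by more
    than 0.5 mmHg (or 2% of the trace excursion, whichever is larger). The
    window is [skip_s, onset), falling back to [0, onset) for short
    pre-baselines.
    """
    v = trace.values
    v0 = np.median(v[:5])
    thr = max(0.5, 0.02 * np.ptp(v))
    dep = np.flatnonzero(np.abs(v - v0) > thr)
    if dep.size == 0:
        raise DegenerateInputError("trace never departs from baseline")
    onset = trace.times[dep[0]]
    start = skip_s if onset > 2 * skip_s else 0.0
    if onset <= start:
        raise InvalidSpecError("stimulus onset leaves no baseline window")
    return (start, float(onset))


def percent_change(series: np.ndarray, baseline_window: np.ndarray) -> np.ndarray:
    """Percent signal change relative to the mean over a baseline index window."""
    s = np.asarray(series, dtype=float)
    idx = np.asarray(baseline_window)
    if idx.size == 0:
        raise InvalidSpecError("baseline window is empty")
    ref = s[idx].mean()
    if abs(ref) < 1e-9 * max(np.abs(s).max(), 1.0):
        raise DegenerateInputError("baseline mean is (near) zero")
    return 100.0 * (s - ref) / ref


def compute_cvr(bold: BoldImage4D, petco2_tr: UniformTrace, lag: VoxelMap | None,
                cfg: CvrConfig = CvrConfig(),
                brain_mask: np.ndarray | None = None) -> tuple[VoxelMap, VoxelMap]:
    """CVR (%BOLD/mmHg) and r^2 maps by per-voxel OLS on the TR grid.

    Parameters
    ----------
    bold:
        Denoised BOLD image on the TR grid.
    petco2_tr:
        The aligned end-tidal CO2 trace resampled to the TR grid.
    lag:
        Voxelwise lag map (seconds, relative to the aligned trace); required
        when ``cfg.use_lag_adjustment``; voxels with invalid lag are skipped.
    """
    if brain_mask is None:
        brain_mask = np.ones(bold.grid_shape, bool)
    brain_mask = np.asarray(brain_mask, bool)
    if not brain_mask.any():
        raise EmptyRegionError("brain mask is empty")
    if cfg.use_lag_adjustment and lag is None:
        raise InvalidSpecError("lag map required when use_lag_adjustment is set")

    x_tr = petco2_tr.values
    if x_tr.std() == 0:
        raise DegenerateInputError("end-tidal trace has zero variance")
    tk = bold.times
    lo, hi = (cfg.baseline_window_s if cfg.baseline_window_s is not None
              else baseline_window_from_trace(petco2_tr))
    # half-open window, matching the stimulus convention: a baseline ending at
    # the stimulus onset must not include the onset sample itself
    base_idx = np.flatnonzero((tk >= lo) & (tk < hi))
    if base_idx.size == 0:
        raise InvalidSpecError("baseline window contains no TR samples")

    trace_times = petco2_tr.times
    # the end-tidal trace is piecewise linear between breath samples by
    # construction, so the lag shift uses linear interpolation: any smooth
    # cubic rings at the single-breath transitions and biases the slope down
    t_lo, t_hi = trace_times[0], trace_times[-1]

    shape = bold.grid_shape
    cvr = np.full(shape, np.nan)
    r2 = np.full(shape, np.nan)
    ok = np.zeros(shape, bool)

    for i, j, k in np.argwhere(brain_mask):
        s = bold.data[i, j, k]
        if cfg.use_lag_adjustment:
            if not lag.valid[i, j, k]:
                continue
            L = lag.data[i, j, k]
            t_shift = tk - L
            support = (t_shift >= t_lo) & (t_shift <= t_hi)
            if support.sum() < cfg.min_valid_points:
                continue
            x = np.interp(t_shift[support], trace_times, x_tr)
            y = s[support]
        else:
            n = min(len(s), len(x_tr))
            if n < cfg.min_valid_points:
                continue
            x, y = x_tr[:n], s[:n]
        if x.std() == 0:
            continue
        ref = s[base_idx].mean()
        if abs(ref) < 1e-9 * max(np.abs(s).max(), 1.0):
            continue
        p = 100.0 * (y - ref) / ref
        slope, _ = np.polyfit(x, p, 1)
        if p.std() == 0:
            rr = 0.0
        else:
            rr = float(np.corrcoef(x, p)[0, 1] ** 2)
        cvr[i, j, k] = slope
        r2[i, j, k] = rr
        ok[i, j, k] = True

    return (VoxelMap(cvr, "pct_per_mmHg", ok), VoxelMap(r2, "r2", ok))
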