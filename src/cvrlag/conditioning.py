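"""Temporal conditioning of BOLD series and end-tidal traces.

Four operations prepare the data for lag analysis:

* wavelet denoising of each voxel time course (symlet-4, two decomposition
  levels, hard thresholding with level-dependent noise estimation);
* linear resampling of the per-breath end-tidal trace onto the TR grid;
* alignment of the resampled trace to the mean gray-matter signal by maximum
  Pearson correlation over integer-sample shifts;
* cubic-spline oversampling (default 8x, i.e. a 375 ms grid for a 3 s TR)
  of both traces and voxel series, which sets the lag-map resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pywt
from scipy.interpolate import CubicSpline

from .containers import BoldImage4D, UniformTrace, pearson
from .errors import DegenerateInputError, ExtrapolationError, InvalidSpecError
from .paradigms import EndTidalTrace

#: Median absolute deviation to Gaussian SD conversion factor.
_MAD_TO_SD = 0.6745

THRESHOLD_RULES = ("bayes", "universal", "none")


@dataclass(frozen=True)
class DenoiseConfig:
    """Wavelet denoising settings.

    ``threshold_rule`` selects the level-dependent threshold: ``"bayes"``
    (BayesShrink, data-adaptive), ``"universal"`` (sigma * sqrt(2 ln N)), or
    ``"none"`` (thresholds forced to zero; diagnostic identity path).
    Thresholding is always hard; approximation coefficients are never touched.
    """

    wavelet_name: str = "sym4"
    levels: int = 2
    threshold_rule: str = "bayes"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise InvalidSpecError("levels must be >= 1")
        if self.threshold_rule not in THRESHOLD_RULES:
            raise InvalidSpecError(
                f"threshold_rule must be one of {THRESHOLD_RULES}")


def _level_threshold(detail: np.ndarray, rule: str) -> float:
    if rule == "none":
        return 0.0
    sigma = np.median(np.abs(detail)) / _MAD_TO_SD
    if rule == "universal":
        return float(sigma * np.sqrt(2.0 * np.log(len(detail))))
    # BayesShrink: sigma^2 / sqrt(var - sigma^2); when the detail variance does
    # not exceed the noise estimate the level is considered pure noise and the
    # threshold diverges, zeroing every coefficient.
    excess = max(float(np.var(detail)) - sigma**2, 1e-12)
    return float(sigma**2 / np.sqrt(excess))


def wavelet_denoise(series: np.ndarray, cfg: DenoiseConfig = DenoiseConfig()) -> np.ndarray:
    """Denoise a 1D series by hard-thresholded multilevel wavelet shrinkage.

    The series is decomposed with symmetric boundary extension, each detail
    level is hard-thresholded (|d| <= threshold set to zero) with its own
    noise-scale estimate (median |d| / 0.6745), and the signal reconstructed
    to the original length.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise InvalidSpecError("wavelet_denoise expects a 1D series")
    if len(x) < 2**cfg.levels:
        raise InvalidSpecError(
            f"series of length {len(x)} too short for {cfg.levels} levels")
    if not np.all(np.isfinite(x)):
        raise InvalidSpecError("series contains non-finite values")
    coeffs = pywt.wavedec(x, cfg.wavelet_name, level=cfg.levels, mode="symmetric")
    out = [coeffs[0]]
    for d in coeffs[1:]:
        thr = _level_threshold(d, cfg.threshold_rule)
        dd = d.copy()
        dd[np.abs(dd) <= thr] = 0.0
        out.append(dd)
    rec = pywt.waverec(out, cfg.wavelet_name, mode="symmetric")
    return rec[: len(x)]


def denoise_image(bold: BoldImage4D, cfg: DenoiseConfig = DenoiseConfig(),
                  mask: np.ndarray | None = None) -> BoldImage4D:
    """Apply :func:`wavelet_denoise` to every (in-mask) voxel time course."""
    data = bold.data.copy()
    if mask is None:
        mask = np.ones(bold.grid_shape, dtype=bool)
    vox = data[mask]
    for i in range(vox.shape[0]):
        vox[i] = wavelet_denoise(vox[i], cfg)
    data[mask] = vox
    return BoldImage4D(data=data, tr_s=bold.tr_s, affine=bold.affine)


def resample_trace_to_tr(trace: EndTidalTrace, tr_s: float, nt: int,
                         channel: str = "co2") -> UniformTrace:
    """Linearly interpolate per-breath samples onto the TR grid t = 0..(nt-1)*TR."""
    if channel not in ("co2", "o2"):
        raise InvalidSpecError("channel must be 'co2' or 'o2'")
    if not tr_s > 0 or nt < 2:
        raise InvalidSpecError("need tr_s > 0 and nt >= 2")
    t_end = (nt - 1) * tr_s
    if trace.breath_times[0] > 0 or trace.breath_times[-1] < t_end - 1e-9:
        raise ExtrapolationError(
            f"trace spans [{trace.breath_times[0]:g}, {trace.breath_times[-1]:g}] s "
            f"but the BOLD grid needs [0, {t_end:g}] s")
    values = trace.petco2 if channel == "co2" else trace.peto2
    tk = np.arange(nt) * tr_s
    return UniformTrace(values=np.interp(tk, trace.breath_times, values),
                        dt_s=tr_s, t0_s=0.0)


class AlignmentResult(NamedTuple):
    trace: UniformTrace
    shift_s: float
    r: float


def align_trace_to_gm(trace_tr: UniformTrace, gm_mean: np.ndarray,
                      max_shift_s: float = 30.0) -> AlignmentResult:
    """Shift the trace to maximize its correlation with the mean GM signal.

    Integer-sample shifts in [-max_shift_s, +max_shift_s] are searched; the
    correlation is computed on the overlapping support only and ties are
    broken toward the smallest absolute shift. A positive shift delays the
    trace (the usual case: the vascular response trails the stimulus). The
    returned trace is the full-length shifted trace, edge-padded, with the
    winning correlation (which may be negative; the caller decides what to do
    with an anti-correlated trace).
    """
    g = np.asarray(gm_mean, dtype=float)
    v = trace_tr.values
    if g.std() == 0:
        raise DegenerateInputError("mean GM signal has zero variance")
    if v.std() == 0:
        raise DegenerateInputError("trace has zero variance")
    dt = trace_tr.dt_s
    if max_shift_s < dt:
        raise InvalidSpecError("max_shift_s must be at least one sample")
    K = int(np.floor(max_shift_s / dt + 1e-9))
    n = min(len(v), len(g))
    best_r, best_k = -np.inf, 0
    for k in sorted(range(-K, K + 1), key=lambda s: (abs(s), s)):
        if k >= 0:
            a, b = v[: n - k], g[k:n]
        else:
            a, b = v[-k:n], g[: n + k]
        if len(a) < 3 or a.std() == 0 or b.std() == 0:
            continue
        r = pearson(a, b)
        if r > best_r:
            best_r, best_k = r, k
    if not np.isfinite(best_r):
        raise DegenerateInputError("no admissible shift had computable correlation")
    if best_k >= 0:
        shifted = np.concatenate([np.full(best_k, v[0]), v[: len(v) - best_k]])
    else:
        shifted = np.concatenate([v[-best_k:], np.full(-best_k, v[-1])])
    return AlignmentResult(
        trace=UniformTrace(values=shifted, dt_s=dt, t0_s=trace_tr.t0_s),
        shift_s=best_k * dt, r=best_r)


def oversample(series: np.ndarray, dt_s: float, factor: int,
               t0_s: float = 0.0) -> UniformTrace:
    """Cubic-spline interpolation onto a grid ``factor`` times finer.

    Output covers the original span with ``factor * (n - 1) + 1`` samples;
    the original sample values are preserved exactly (the spline interpolates
    its nodes).
    """
    x = np.asarray(series, dtype=float)
    if factor < 1:
        raise InvalidSpecError("oversampling factor must be >= 1")
    if x.ndim != 1 or len(x) < 4:
        raise InvalidSpecError("need a 1D series of length >= 4")
    if factor == 1:
        return UniformTrace(values=x.copy(), dt_s=dt_s, t0_s=t0_s)
    t = np.arange(len(x)) * dt_s
    fine = np.arange(factor * (len(x) - 1) + 1) * (dt_s / factor)
    values = CubicSpline(t, x)(fine)
    # guarantee exact node preservation against spline round-off
    values[::factor] = x
    return UniformTrace(values=values, dt_s=dt_s / factor, t0_s=t0_s)


def oversample_image(bold: BoldImage4D, factor: int) -> BoldImage4D:
    """Oversample every voxel time course of a 4D image by ``factor``."""
    if factor < 1:
        raise InvalidSpecError("oversampling factor must be >= 1")
    if factor == 1:
        return bold
    t = bold.times
    fine = np.arange(factor * (bold.nt - 1) + 1) * (bold.tr_s / factor)
    flat = bold.data.reshape(-1, bold.nt)
    out = CubicSpline(t, flat, axis=1)(fine)
    out[:, ::factor] = flat
    return BoldImage4D(data=out.reshape(bold.grid_shape + (len(fine),)),
                       tr_s=bold.tr_s / factor, affine=bold.affine)
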