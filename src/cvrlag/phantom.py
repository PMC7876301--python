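"""Synthetic 4D BOLD phantoms with known per-voxel lag and CVR.

The phantom is a concentric slab: an outer gray-matter (GM) shell around an
inner white-matter (WM) core, with zero-signal background, replicated over
slices. Each tissue voxel responds to the end-tidal stimulus through a simple
forward model: fractional BOLD change proportional to the CO2 (and, for BOOST,
O2) excursion from the pre-stimulus baseline, delayed by a voxel-specific
hemodynamic lag and optionally smoothed by a causal one-sided exponential
dispersion kernel:

    S_v(k TR) = S0 * (1 + (c_v/100) dPco2(k TR - tau_v)
                        + (g_o2/100) dPo2(k TR - tau_v)) (*) h_tau
                + noise + drift

with S0 = 1000 arbitrary units (CVR is a percent change, so S0 cancels).
Per-voxel lags tau_v and amplitudes c_v are drawn from tissue-specific
truncated normals (both bounded below at zero: negative lag has no meaning in
this model, and negative reactivity is the vascular-steal regime this phantom
deliberately does not emulate). Gaussian white noise with SD S0/tsnr is added
to tissue voxels (AR(1)-correlated noise is available for robustness tests);
background voxels carry only S0 plus drift.

Defaults encode the study conditions the phantom emulates: 3 s TR, a ~10 s
GM-to-WM lag offset (12 s vs 22 s), and GM/WM CVR of 0.38/0.17 %BOLD/mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import BoldImage4D, VoxelMap
from .errors import InvalidSpecError
from .paradigms import EndTidalTrace

#: Baseline tissue signal, arbitrary units.
S0 = 1000.0

#: Window (s from trace start) over which the pre-stimulus baseline pressures
#: are estimated; must sit inside the shortest paradigm's pre-baseline.
BASELINE_EST_S = 30.0

LABEL_BACKGROUND, LABEL_GM, LABEL_WM = 0, 1, 2


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, ground-truth distributions and noise of a synthetic run.

    Lag means/SDs are seconds; CVR means/SDs are %BOLD/mmHg. ``tsnr`` is the
    temporal signal-to-noise ratio (0 disables noise). ``lag_bounds_s``
    truncates the per-voxel lag distribution (lower bound never below 0).
    """

    grid_shape: tuple[int, int, int] = (24, 24, 4)
    tr_s: float = 3.0
    gm_lag_mean_s: float = 12.0
    gm_lag_sd_s: float = 5.0
    wm_lag_mean_s: float = 22.0
    wm_lag_sd_s: float = 5.0
    gm_cvr_mean: float = 0.38
    gm_cvr_sd: float = 0.22
    wm_cvr_mean: float = 0.17
    wm_cvr_sd: float = 0.11
    o2_gain: float = 0.01
    dispersion_tau_gm_s: float = 0.0
    dispersion_tau_wm_s: float = 0.0
    tsnr: float = 50.0
    ar1_coef: float = 0.0
    drift_pct_per_min: float = 0.0
    lag_bounds_s: tuple[float, float] = (0.0, np.inf)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(n < 1 for n in self.grid_shape):
            raise InvalidSpecError("grid_shape must be three positive integers")
        if not self.tr_s > 0:
            raise InvalidSpecError("tr_s must be positive")
        for name in ("gm_lag_sd_s", "wm_lag_sd_s", "gm_cvr_sd", "wm_cvr_sd",
                     "dispersion_tau_gm_s", "dispersion_tau_wm_s"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be >= 0")
        if self.tsnr < 0:
            raise InvalidSpecError("tsnr must be >= 0 (0 = noiseless)")
        if not -1 < self.ar1_coef < 1:
            raise InvalidSpecError("ar1_coef must lie in (-1, 1)")
        lo, hi = self.lag_bounds_s
        if lo < 0 or hi <= lo:
            raise InvalidSpecError("lag_bounds_s must satisfy 0 <= lo < hi")


@dataclass
class PhantomTruth:
    """Ground truth of a phantom run, for parameter-recovery scoring."""

    true_lag: VoxelMap
    true_cvr: VoxelMap
    tissue_label: VoxelMap
    gm_prob: np.ndarray
    wm_prob: np.ndarray

    def __post_init__(self) -> None:
        gp = np.asarray(self.gm_prob, float)
        wp = np.asarray(self.wm_prob, float)
        if np.any(gp + wp > 1 + 1e-12):
            raise InvalidSpecError("gm_prob + wm_prob must not exceed 1")
        tissue = self.tissue_label.data > 0
        if not np.all(np.isfinite(self.true_lag.data[tissue])):
            raise InvalidSpecError("true lag must be finite in tissue")

    @property
    def gm_mask(self) -> np.ndarray:
        return self.tissue_label.data == LABEL_GM

    @property
    def wm_mask(self) -> np.ndarray:
        return self.tissue_label.data == LABEL_WM


def slab_geometry(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Tissue labels of the concentric slab: GM shell around a WM core.

    In-plane, the WM core fills the central 35% of the normalized radius and
    the GM shell extends to 85%; the pattern repeats on every slice.
    """
    nx, ny, nz = grid_shape
    x = (np.arange(nx) - (nx - 1) / 2) / (nx / 2)
    y = (np.arange(ny) - (ny - 1) / 2) / (ny / 2)
    r = np.sqrt(x[:, None] ** 2 + y[None, :] ** 2)
    plane = np.zeros((nx, ny), dtype=np.int8)
    plane[r <= 0.85] = LABEL_GM
    plane[r <= 0.35] = LABEL_WM
    return np.repeat(plane[:, :, None], nz, axis=2)


def _truncated_normal(mean: float, sd: float, lo: float, hi: float,
                      size: int, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def draw_truth(spec: PhantomSpec, rng: np.random.Generator | None = None) -> PhantomTruth:
    """Draw per-voxel ground-truth lag/CVR maps for a phantom spec."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    label = slab_geometry(spec.grid_shape)
    lag = np.full(spec.grid_shape, np.nan)
    cvr = np.full(spec.grid_shape, np.nan)
    lo, hi = spec.lag_bounds_s
    for lab, lag_m, lag_s, cvr_m, cvr_s in (
        (LABEL_GM, spec.gm_lag_mean_s, spec.gm_lag_sd_s, spec.gm_cvr_mean, spec.gm_cvr_sd),
        (LABEL_WM, spec.wm_lag_mean_s, spec.wm_lag_sd_s, spec.wm_cvr_mean, spec.wm_cvr_sd),
    ):
        m = label == lab
        n = int(m.sum())
        lag[m] = _truncated_normal(lag_m, lag_s, lo, hi, n, rng)
        cvr[m] = _truncated_normal(cvr_m, cvr_s, 0.0, np.inf, n, rng)
    tissue = label > 0
    return PhantomTruth(
        true_lag=VoxelMap(lag, "seconds", tissue),
        true_cvr=VoxelMap(cvr, "pct_per_mmHg", tissue),
        tissue_label=VoxelMap(label.astype(float), "label", np.ones_like(label, bool)),
        gm_prob=(label == LABEL_GM).astype(float),
        wm_prob=(label == LABEL_WM).astype(float),
    )


def _dispersion_kernel(tau_s: float, dt_s: float) -> np.ndarray:
    """Causal one-sided exponential, discretized and normalized to unit sum."""
    n = max(int(np.ceil(8 * tau_s / dt_s)), 2)
    k = np.exp(-np.arange(n) * dt_s / tau_s)
    return k / k.sum()


def simulate_bold(
    trace: EndTidalTrace,
    spec: PhantomSpec,
    truth: PhantomTruth | None = None,
) -> tuple[BoldImage4D, PhantomTruth, EndTidalTrace]:
    """Simulate a 4D BOLD acquisition responding to an end-tidal trace.

    Parameters
    ----------
    trace:
        The per-breath stimulus; must span the scan implied by ``spec``.
    spec:
        Phantom geometry, truth distributions and noise settings.
    truth:
        Optional pre-drawn ground truth (e.g. to re-simulate the same voxel
        population with a global delay added); when omitted, truth is drawn
        from ``spec`` with its seed.

    Returns
    -------
    (bold, truth, trace):
        The simulated image, the ground truth used, and the exact stimulus
        trace the simulation consumed.
    """
    rng = np.random.default_rng(spec.seed)
    if truth is None:
        truth = draw_truth(spec, rng)
    elif truth.tissue_label.shape != spec.grid_shape:
        raise InvalidSpecError("supplied truth does not match grid_shape")

    nt = int(np.floor(trace.span_s / spec.tr_s)) + 1
    if nt < 16:
        raise InvalidSpecError("trace too short for a meaningful scan")
    tk = np.arange(nt) * spec.tr_s

    base_sel = trace.breath_times <= BASELINE_EST_S
    dco2 = trace.petco2 - trace.petco2[base_sel].mean()
    do2 = trace.peto2 - trace.peto2[base_sel].mean()

    label = truth.tissue_label.data.astype(int)
    data = np.full(spec.grid_shape + (nt,), S0, dtype=float)
    drift = S0 * (spec.drift_pct_per_min / 100.0) * (tk / 60.0)
    data += drift  # background and tissue alike carry the drift

    for lab, disp_tau in ((LABEL_GM, spec.dispersion_tau_gm_s),
                          (LABEL_WM, spec.dispersion_tau_wm_s)):
        mask = label == lab
        idx = np.argwhere(mask)
        if idx.size == 0:
            continue
        taus = truth.true_lag.data[mask]
        amps = truth.true_cvr.data[mask]
        if disp_tau > 0:
            dtf = spec.tr_s / 8.0
            tf = np.arange(0.0, tk[-1] + dtf, dtf)
            kern = _dispersion_kernel(disp_tau, dtf)
        for (i, j, k), tau, c in zip(idx, taus, amps):
            if disp_tau > 0:
                resp = (c / 100.0) * np.interp(tf - tau, trace.breath_times, dco2,
                                               left=0.0, right=dco2[-1])
                resp += (spec.o2_gain / 100.0) * np.interp(
                    tf - tau, trace.breath_times, do2, left=0.0, right=do2[-1])
                resp = np.convolve(resp, kern)[: len(tf)]
                resp = np.interp(tk, tf, resp)
            else:
                resp = (c / 100.0) * np.interp(tk - tau, trace.breath_times, dco2,
                                               left=0.0, right=dco2[-1])
                resp += (spec.o2_gain / 100.0) * np.interp(
                    tk - tau, trace.breath_times, do2, left=0.0, right=do2[-1])
            data[i, j, k, :] += S0 * resp

    if spec.tsnr > 0:
        tissue = label > 0
        n_tissue = int(tissue.sum())
        if spec.ar1_coef != 0:
            from scipy.signal import lfilter

            burn = 50
            innov = rng.standard_normal((n_tissue, nt + burn))
            # stationary AR(1) with unit marginal variance after burn-in
            eps = lfilter([np.sqrt(1 - spec.ar1_coef**2)], [1, -spec.ar1_coef],
                          innov, axis=1)[:, burn:]
        else:
            eps = rng.standard_normal((n_tissue, nt))
        data[tissue] += (S0 / spec.tsnr) * eps

    bold = BoldImage4D(data=data, tr_s=spec.tr_s)
    return bold, truth, trace
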