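# Methods

This note records the models, parameter choices and numerical decisions
behind `cvrlag`, and what the synthetic-phantom validation does and does not
demonstrate about real data.

## Stimulus model

End-tidal traces are generated per breath (default breath period 3 s, equal
to the TR so that resampling to the scan grid is exact). Three paradigms are
modelled, with targets in mmHg:

| paradigm | CO₂ baseline | CO₂ excursion | O₂ step | timing |
|---|---|---|---|---|
| block | 36 | +8 | — | 120 s pre, 90 s step, 120 s post (330 s) |
| ramp | 35 | −4 then +16 | — | 87 s pre, 60 s hypocapnia + 300 s linear rise, 60 s post (507 s) |
| boost | 39 | +8 | +159 on a 111 baseline | as block |

Transitions are idealized as single-breath steps. A prospective gas-targeting
system reaches its end-tidal targets within a few breaths; collapsing that to
one breath makes the stimulus an upper bound on sharpness and pushes all
physiological smoothing into the phantom's dispersion kernel, where it is
explicit and controllable. The ramp's return to baseline is likewise a
single-breath step (its exact shape does not enter any estimate, since the
ramp analysis window ends at the peak). The total ramp duration was split
87 + 360 + 60 s so that the trace exactly covers a 507 s acquisition.

## Phantom forward model

The phantom is a concentric slab — an elliptical GM annulus (normalized
in-plane radius 0.35–0.85) around a WM core, replicated across slices — so GM
and WM masks are non-trivial but exactly known. Each tissue voxel follows

    S_v(kTR) = S0 · (1 + c_v/100 · ΔPco2(kTR − τ_v)
                       + g_o2/100 · ΔPo2(kTR − τ_v)) ⊛ h_disp
               + ε + drift,

with S0 = 1000 arbitrary units (CVR is a percent change, so S0 cancels),
ΔP(·) the linear interpolation of the per-breath excursions from the
pre-stimulus baseline (estimated as the mean over the first 30 s of the
trace), and h_disp a causal one-sided exponential of unit area (time constant
per tissue; 0 means a pure shift). Noise ε is white Gaussian with SD S0/tsnr
(an AR(1) option exists for robustness experiments); background voxels carry
only S0 plus drift, so they are exactly degenerate for the correlation
search.

Per-voxel ground truth is drawn from tissue-specific truncated normals:

* lag: GM 12 ± 5 s, WM 22 ± 5 s, truncated at ≥ 0 (optionally bounded above,
  e.g. (0, 30) s for resolution tests). The 10 s GM→WM offset is the
  tissue contrast the recovery tests target; the 5 s spread was chosen as a
  plausible within-tissue heterogeneity that keeps the two distributions
  clearly distinct.
* CVR amplitude: GM 0.38 ± 0.22, WM 0.17 ± 0.11 %BOLD/mmHg, truncated at
  ≥ 0. Truncation is a deliberate modelling choice: negative reactivity is
  the vascular-steal regime, which this phantom intentionally does not
  emulate (steal is a spatial redistribution phenomenon, not a per-voxel
  draw), and a negative-amplitude voxel has no defined lag under a
  signed-maximum correlation search. Recovery is therefore always scored
  against the drawn truth maps, not against the nominal means, which the
  truncation shifts slightly upward.
* the hyperoxic gain g_o2 defaults to 0.01 %BOLD/mmHg. No quantitative value
  is established for this coefficient; it is a configurable placeholder and
  the boost-paradigm CVR maps consequently overestimate CVR by design (the
  O₂-driven signal is not separated out — the analysis reproduces that
  behavior rather than correcting it).

With tsnr = 50 and these amplitudes the per-volume contrast-to-noise is
~1.5 for an average GM voxel and ~0.7 for WM — a deliberately hard noise
regime (see *Limitations*).

## Denoising

Voxel time courses are denoised by a multilevel discrete wavelet transform
(symlet-4, 2 levels, symmetric boundary extension). Each detail level j gets
its own noise scale σ̂_j = median(|d_j|)/0.6745 and a hard threshold
(|d| ≤ thr → 0); approximation coefficients are never touched. Two rules are
provided: BayesShrink (default), thr = σ̂²/√(max(var(d) − σ̂², ε)), which
adapts to how much structure a level carries and diverges (zeroing the
level) when a level is pure noise; and the universal threshold
σ̂·√(2 ln N). A third rule, `none`, forces all thresholds to zero and exists
as the diagnostic identity path for verifying perfect reconstruction.

Two properties matter downstream. First, on noiseless model signals the
BayesShrink thresholds collapse to ~0 (the detail coefficients are sparse and
their median magnitude vanishes), so denoising is a near-identity and cannot
corrupt noiseless recovery tests. Second, on white noise the two thresholding
rules remove roughly the upper three quarters of the spectrum (the detail
bands of a 2-level transform) but by construction cannot touch
approximation-band noise. The residual noise is therefore concentrated at low
frequencies — exactly the band the stimulus response occupies. This is
quantified below because it dominates the noisy-lag error budget.

## Alignment and lag mapping

The per-breath CO₂ trace is linearly resampled to the TR grid and aligned to
the mean GM signal by maximizing Pearson correlation over integer-TR shifts
within ±30 s (ties toward the smallest shift; the winning correlation is
reported signed, so an anti-correlated trace is visible to the caller). All
lags are reported **relative to the aligned trace**; absolute lags embed this
alignment convention, so only differences (e.g. WM − GM) are comparable
across runs. Recovery against phantom truth adds the recorded alignment shift
back.

Trace and BOLD are then oversampled 8× by cubic spline (375 ms grid for a
3 s TR) — the mechanism that sets the lag resolution — and the lag of each
voxel is the argmax over candidate lags on that grid of the Pearson
correlation with the regressor, computed on the overlapping support only
(candidates with less than 25% overlap are excluded). Peak picking stays on
the discrete grid with no parabolic sub-step refinement: 375 ms is already
far below any effect of interest, and the discrete search is exactly
verifiable against a brute-force oracle. Ties break toward the smallest
absolute lag; a peak at a search boundary invalidates the voxel rather than
clamping it, to avoid pile-up artifacts in lag histograms. A voxel is also
invalid if degenerate (zero variance) or if its peak correlation falls below
`r_threshold` (default 0.3).

The search window defaults to [−10, +90] s: tissue delays under a
progressive (ramp) stimulus extend far beyond the GM values, so the window
must admit lags past 60 s; small negative lags are allowed because the
alignment reference is the bulk GM response, which some voxels lead.

The optimized regressor is built by one refinement pass (configurable):
voxels correlating with the probe at r ≥ 0.3 (restricted to GM by default)
are shifted back by their estimated lag (per-voxel cubic interpolation),
z-scored, and averaged sample-wise over their common support; the z-scored
average becomes the final regressor, and the last pass's voxel count is
recorded. With ~10³ contributing voxels the regressor's own noise is
negligible; its benefit on real data is to absorb the average hemodynamic
response shape that the raw CO₂ trace lacks.

## CVR regression

Percent signal change is computed against the mean over a pre-stimulus
baseline window. By default the window is derived from the trace itself —
from 15 s after the start (discarding settling samples) to the stimulus
onset, detected as the first departure of more than max(0.5 mmHg, 2% of the
excursion) from the initial level — so the same default is correct for the
block (onset 120 s) and ramp (onset 87 s) timings. The window is half-open
at the onset so the first stimulus sample never contaminates the reference.

CVR is the OLS slope of percent signal against the CO₂ trace on the **TR
grid** (not the oversampled grid), keeping residual degrees of freedom equal
to the number of acquired volumes; r² accompanies each slope. For the
lag-adjusted map the trace is shifted by the voxel's estimated lag using
**linear** interpolation on the overlapping support. Linear, not cubic, is
deliberate: the end-tidal trace is piecewise linear between breath samples by
construction, so a linear shift is exact, whereas any smooth cubic (C²
spline or monotone Hermite) rings or rounds the single-breath transitions
and measurably attenuates the mean slope (by ~0.3% for the block stimulus —
larger than the entire lag-quantization residual). Voxels with fewer than 4
overlapping samples, or an invalid lag, are invalidated; the same
"fewer than 4 data points" rule is applied per voxel in group averaging,
where it is primarily meant.

## Tissue statistics

Masks come from probability maps with inclusive thresholds (prob ≥ 50% GM,
≥ 90% WM). Summaries report mean and SD (n−1 denominator) plus a cumulative
percent-frequency histogram normalized to end exactly at 100 (default bins:
4 s for lag, 0.05 %/mmHg for CVR; out-of-range values are clipped into the
edge bins so no mass is lost). Group averaging over runs counts valid
entries only and invalidates voxels with fewer than 4 contributions. Group
analysis assumes maps already share a grid; on real data, spatial
normalization must be applied externally beforehand.

## What the phantom validation shows — and what it does not

The recovery tests demonstrate, end to end: exact-grid lag recovery without
noise (every valid voxel within one 375 ms step, including the regressor
refinement and alignment stages); unbiased CVR recovery with known lags;
preservation of the GM–WM lag offset under a global delay; and byte-level
determinism of the file pipeline. The phantom deliberately omits motion,
slice-timing offsets, cardiac/respiratory nuisance cycles, vascular steal,
spatially correlated noise, and partial-volume mixtures; passing these tests
therefore says nothing about robustness to those effects, only that the
estimators are correct under their own model.

One noisy-regime behavior deserves explicit quantification rather than
burial. At tsnr 50 with block stimulation, per-voxel lag error
**medians** are small (GM +0.4 s, WM +0.8 s) but the **means** are skewed
upward (GM ≈ +1.6 s, WM ≈ +3.4 s), so a masked-mean WM−GM offset recovers as
≈ 9.8–13.4 s across seeds rather than tightly around 10 s. The mechanism is
structural: a boxcar's correlation function is triangular with a ~65 s
half-width, so a 10 s mis-lag costs only ~15% of r; the noise that survives
wavelet denoising is concentrated in the approximation band, the same band
as the response, and occasionally raises a far-away candidate above the true
peak (such voxels still show r ≈ 0.35–0.7, so no threshold separates them);
and the asymmetric [−10, +90] s window leaves far more room for positive
than negative wander. The same selection effect inflates noisy lag-adjusted
WM CVR by up to ~+0.01–0.02 %/mmHg, because the regression reuses the shift
that was chosen by maximizing correlation on the same noise. These are
properties of correlation-based lag mapping on slow block designs at low
contrast-to-noise — they shrink rapidly with tsnr and with stimulus
sharpness — and are reported by the acceptance script rather than hidden by
a robust estimator, because the package implements the standard
masked-mean/argmax estimators as practiced.

## Numerical details

* All randomness flows through `numpy.random.Generator` seeded per run;
  the analysis itself is deterministic, and NIfTI outputs are written
  uncompressed so repeated runs are byte-identical.
* Oversampling preserves node values exactly (enforced after spline
  evaluation against round-off).
* Correlation searches use prefix sums for segment moments plus one matrix
  product per candidate lag; the production path is tested to 1e−10 against
  a direct `np.corrcoef` loop.
* Degenerate inputs are contractual: constant voxels are flagged, not
  raised; constant traces/GM means raise typed errors before any
  computation.
* Problem sizes used in the shipped tests and acceptance script — 24×24×4
  voxels (~1330 in tissue) and 110–170 volumes — were chosen so a full
  phantom cycle completes in seconds while leaving ≥ 10² voxels per tissue
  for distributional checks.
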