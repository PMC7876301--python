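# cvrlag

Lag-resolved cerebrovascular reactivity (CVR) mapping from BOLD gas-challenge
data, with a synthetic respiratory-challenge phantom for end-to-end validation.

## The problem

Cerebrovascular reactivity is the change in cerebral blood flow — observed
through the BOLD signal — per unit change in arterial CO₂, expressed here as
Δ%BOLD/mmHg. A hypercapnic breathing challenge (a boxcar or ramped rise in
end-tidal CO₂, P_ET_CO₂) drives vasodilation, but the response of each voxel
trails the stimulus by a hemodynamic lag that differs strongly between gray
matter (GM) and white matter (WM). Ignoring that lag biases CVR downward,
especially in late-responding WM; estimating it voxel by voxel both corrects
the CVR map and is informative in itself (arterial transit, blood
redistribution, CO₂ diffusion kinetics). Adding a simultaneous hyperoxic step
(a combined CO₂+O₂ "boost" block) turns the inflowing blood into an endogenous
contrast bolus that shortens apparent delays without changing the GM–WM
offset.

`cvrlag` implements the full analysis chain for such experiments:

1. **Temporal denoising** of every voxel time course: symlet-4 wavelet,
   2 decomposition levels, hard thresholding with level-dependent noise
   estimation (BayesShrink by default, `σ̂_j = median(|d_j|)/0.6745`).
2. **Trace conditioning**: the per-breath end-tidal trace is linearly
   resampled to the TR grid and aligned to the mean GM signal by maximum
   Pearson correlation over integer shifts.
3. **Lag mapping**: both the trace and the BOLD data are oversampled 8×
   (375 ms grid for a 3 s TR). The aligned CO₂ trace serves as the initial
   probe; voxels correlating with it at `r ≥ 0.3` are shifted back by their
   lag, z-scored and averaged into an *optimized regressor* (the
   rapid-interpolation-at-progressive-time-delays refinement scheme). The lag
   of each voxel is then `argmax_τ corr(S_v(t), reg(t − τ))` over
   `τ ∈ [−10, 90] s` on the oversampled grid.
4. **CVR mapping**: per voxel, ordinary least squares of the percent signal
   change against the (optionally lag-shifted) P_ET_CO₂ trace on the TR grid;
   the slope is CVR in %BOLD/mmHg, with the fit's r² alongside. Both
   lag-adjusted and unadjusted maps are produced.
5. **Tissue statistics**: GM/WM masks from probability maps (inclusive
   thresholds, 50% GM / 90% WM), mean ± SD, cumulative percent-frequency
   histograms, group averaging with a minimum-coverage filter (≥ 4
   contributing runs per voxel), and recovery scoring against phantom truth.

Because raw 7T gas-challenge data are rarely shareable, the package ships a
first-class synthetic data module: three stimulus paradigms (block
hypercapnia, hypocapnia-then-ramp, and the CO₂+O₂ boost block) and a 4D BOLD
phantom whose per-voxel lags and CVR amplitudes are drawn from tissue-specific
truncated normals, so every stage is testable by parameter recovery.

## Worked example

Simulate a noisy block-hypercapnia phantom (24×24×4 voxels, TR 3 s,
tSNR 50), run the pipeline, and score recovery:

```
cvrlag simulate --paradigm block --out sim --seed 7 --tsnr 50
cvrlag run --bold sim/bold.nii --trace sim/trace.tsv \
           --gm sim/gm_prob.nii --wm sim/wm_prob.nii --out out
cvrlag report --est out --truth sim
```

The `run` step prints the alignment shift and the provenance of the final
regressor:

```
"alignment_shift_s": 12.0,
"regressor": {"provenance": "OPTIMIZED", "n_voxels_used": 1020}
```

The trace was delayed 12 s to match the bulk GM response, and 1020 GM voxels
passed the correlation threshold and contributed to the optimized regressor.
`out/summary.json` then holds the tissue summaries (lag is reported relative
to the aligned trace, so GM sits near zero by construction):

```
GM LAG  1.849 ± 7.868  n 1029      GM CVR 0.419 ± 0.188
WM LAG 12.514 ± 10.197 n 175       WM CVR 0.225 ± 0.091
```

i.e. the ~10 s GM→WM lag offset and the roughly twofold GM/WM CVR ratio of
the generator are recovered under noise. `report` compares against the stored
ground truth (adding the alignment shift back to the lag map):

```
"GM.cvr": {"bias": -0.0043, "rmse": 0.056, "n": 1029}
"WM.lag": {"bias":  2.24,   "rmse": 9.93,  "n": 175}
```

Noise-free recovery is much tighter: with `--tsnr 0` every valid voxel's lag
is recovered to within one oversampled step (0.375 s) and tissue-mean CVR to
within 10⁻³ %BOLD/mmHg.

## Layout

```
src/cvrlag/
  paradigms.py     end-tidal stimulus traces (block / ramp / boost)
  phantom.py       synthetic 4D BOLD generator with ground truth
  conditioning.py  wavelet denoising, resampling, alignment, oversampling
  lagmap.py        correlation lag search and optimized-regressor refinement
  cvr.py           percent-change normalization and CVR regression
  tissue.py        masks, distributions, group maps, recovery reports
  pipeline.py      in-memory `analyze` core and file-based `run_pipeline`
  cli.py           `cvrlag simulate | run | report`
  io.py            trace TSV and NIfTI reading/writing
docs/methods.md    modelling choices, parameters, limitations
```
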