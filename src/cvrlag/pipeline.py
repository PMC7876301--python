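"""End-to-end pipeline: denoise -> align -> lag map -> lag-corrected CVR.

`analyze` is the in-memory core; `run_pipeline` wraps it with file I/O,
configuration and a reproducibility manifest. Given identical inputs the
pipeline is fully deterministic (there is no randomness in the analysis
itself; the seed only labels the run).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import BoldImage4D, UniformTrace, VoxelMap
from .conditioning import (DenoiseConfig, align_trace_to_gm, denoise_image,
                           oversample, oversample_image, resample_trace_to_tr)
from .cvr import CvrConfig, baseline_window_from_trace, compute_cvr
from .errors import InvalidSpecError
from .io import (load_bold, load_prob_map, read_trace, save_map, write_json,
                 write_regressor)
from .lagmap import (LagAnalysisConfig, Regressor, build_optimized_regressor,
                     compute_lag_map)
from .paradigms import EndTidalTrace
from .tissue import DEFAULT_CVR_BINS, DEFAULT_LAG_BINS, binarize_mask, tissue_summary

log = logging.getLogger("cvrlag")

GM_THRESHOLD_PCT = 50.0
WM_THRESHOLD_PCT = 90.0


@dataclass
class PipelineConfig:
    """Paths and per-stage settings of one pipeline run."""

    bold_path: str = ""
    trace_path: str = ""
    gm_prob_path: str = ""
    wm_prob_path: str = ""
    out_dir: str = "."
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    lag: LagAnalysisConfig = field(default_factory=LagAnalysisConfig)
    cvr: CvrConfig = field(default_factory=CvrConfig)
    gm_threshold_pct: float = GM_THRESHOLD_PCT
    wm_threshold_pct: float = WM_THRESHOLD_PCT
    max_shift_s: float = 30.0
    probe_only: bool = False
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        for key, sub in (("denoise", DenoiseConfig), ("lag", LagAnalysisConfig),
                         ("cvr", CvrConfig)):
            if key in raw and isinstance(raw[key], dict):
                if key == "cvr" and "baseline_window_s" in raw[key]:
                    raw[key]["baseline_window_s"] = tuple(raw[key]["baseline_window_s"])
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class PipelineResult:
    """In-memory outputs of one analysis run."""

    lag: VoxelMap
    rmap: VoxelMap
    cvr_adjusted: VoxelMap | None
    r2_adjusted: VoxelMap | None
    cvr_unadjusted: VoxelMap
    r2_unadjusted: VoxelMap
    regressor: Regressor
    alignment_shift_s: float
    alignment_r: float
    petco2_aligned_tr: UniformTrace
    gm_mask: np.ndarray
    wm_mask: np.ndarray
    summaries: list


def analyze(bold: BoldImage4D, trace: EndTidalTrace, gm_prob: np.ndarray,
            wm_prob: np.ndarray,
            denoise_cfg: DenoiseConfig = DenoiseConfig(),
            lag_cfg: LagAnalysisConfig = LagAnalysisConfig(),
            cvr_cfg: CvrConfig = CvrConfig(),
            gm_threshold_pct: float = GM_THRESHOLD_PCT,
            wm_threshold_pct: float = WM_THRESHOLD_PCT,
            max_shift_s: float = 30.0,
            probe_only: bool = False) -> PipelineResult:
    """Run the full analysis on in-memory inputs.

    Stages: voxelwise wavelet denoising; end-tidal trace resampling to the TR
    and alignment to the mean GM signal; 8x oversampling of trace and BOLD;
    probe (aligned CO2) regressor, optionally refined into the optimized
    regressor from high-correlation GM voxels; voxelwise lag and r maps;
    lag-adjusted and unadjusted CVR/r^2 maps on the TR grid; GM/WM summaries.
    """
    gm_mask = binarize_mask(np.asarray(gm_prob, float), gm_threshold_pct)
    wm_mask = binarize_mask(np.asarray(wm_prob, float), wm_threshold_pct)
    brain_mask = gm_mask | wm_mask
    if not brain_mask.any():
        raise InvalidSpecError("GM/WM masks are empty at the given thresholds")

    log.info("denoising %d voxels", int(brain_mask.sum()))
    bold_dn = denoise_image(bold, denoise_cfg, mask=brain_mask)

    gm_mean = bold_dn.data[gm_mask].mean(axis=0)
    trace_tr = resample_trace_to_tr(trace, bold.tr_s, bold.nt, channel="co2")
    aligned, shift_s, align_r = align_trace_to_gm(trace_tr, gm_mean, max_shift_s)
    log.info("trace aligned to GM mean: shift %+.1f s (r=%.3f)", shift_s, align_r)

    factor = lag_cfg.oversample_factor
    probe_tr = oversample(aligned.values, aligned.dt_s, factor)
    probe = Regressor.from_series(probe_tr.values, probe_tr.dt_s,
                                  t0_s=probe_tr.t0_s, provenance="PROBE_PETCO2")
    bold_over = oversample_image(bold_dn, factor)

    if probe_only:
        reg = probe
    else:
        reg = build_optimized_regressor(bold_over, probe, gm_mask, lag_cfg)
        log.info("optimized regressor from %d voxels", reg.n_voxels_used)

    lag, rmap = compute_lag_map(bold_over, reg, lag_cfg, brain_mask)

    # the baseline window is defined on the acquisition timeline, so it is
    # derived from the unaligned trace (the aligned one has a delayed onset)
    window = (cvr_cfg.baseline_window_s
              if cvr_cfg.baseline_window_s is not None
              else baseline_window_from_trace(trace_tr))
    cvr_un, r2_un = compute_cvr(
        bold_dn, aligned, lag,
        CvrConfig(baseline_window_s=window, use_lag_adjustment=False,
                  min_valid_points=cvr_cfg.min_valid_points),
        brain_mask)
    if cvr_cfg.use_lag_adjustment:
        cvr_adj, r2_adj = compute_cvr(
            bold_dn, aligned, lag,
            CvrConfig(baseline_window_s=window, use_lag_adjustment=True,
                      min_valid_points=cvr_cfg.min_valid_points),
            brain_mask)
    else:
        cvr_adj, r2_adj = None, None

    summaries = []
    tables = [("LAG", lag, DEFAULT_LAG_BINS),
              ("CVR_UNADJUSTED", cvr_un, DEFAULT_CVR_BINS),
              ("R2_UNADJUSTED", r2_un, np.linspace(0, 1, 21))]
    if cvr_adj is not None:
        tables += [("CVR", cvr_adj, DEFAULT_CVR_BINS),
                   ("R2", r2_adj, np.linspace(0, 1, 21))]
    for tname, mask in (("GM", gm_mask), ("WM", wm_mask)):
        for pname, vmap, bins in tables:
            try:
                summaries.append(tissue_summary(vmap, mask, bins, tname, pname))
            except Exception:
                log.warning("no valid %s voxels in %s", pname, tname)

    return PipelineResult(
        lag=lag, rmap=rmap, cvr_adjusted=cvr_adj, r2_adjusted=r2_adj,
        cvr_unadjusted=cvr_un, r2_unadjusted=r2_un, regressor=reg,
        alignment_shift_s=shift_s, alignment_r=align_r,
        petco2_aligned_tr=aligned, gm_mask=gm_mask, wm_mask=wm_mask,
        summaries=summaries)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """File-based pipeline run; writes maps, summaries and a manifest.

    Returns the manifest dictionary. All outputs are deterministic functions
    of the inputs and configuration.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    for label, p in (("BOLD", cfg.bold_path), ("trace", cfg.trace_path),
                     ("GM probability", cfg.gm_prob_path),
                     ("WM probability", cfg.wm_prob_path)):
        if not Path(p).is_file():
            raise FileNotFoundError(f"{label} input not found: {p}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    bold = load_bold(cfg.bold_path)
    trace = read_trace(cfg.trace_path)
    gm_prob = load_prob_map(cfg.gm_prob_path)
    wm_prob = load_prob_map(cfg.wm_prob_path)

    res = analyze(bold, trace, gm_prob, wm_prob,
                  denoise_cfg=cfg.denoise, lag_cfg=cfg.lag, cvr_cfg=cfg.cvr,
                  gm_threshold_pct=cfg.gm_threshold_pct,
                  wm_threshold_pct=cfg.wm_threshold_pct,
                  max_shift_s=cfg.max_shift_s, probe_only=cfg.probe_only)

    paths = {
        "lag": save_map(res.lag, out / "lag.nii"),
        "rmap": save_map(res.rmap, out / "r.nii"),
        "cvr_unadjusted": save_map(res.cvr_unadjusted, out / "cvr_unadjusted.nii"),
        "r2_unadjusted": save_map(res.r2_unadjusted, out / "r2_unadjusted.nii"),
    }
    if res.cvr_adjusted is not None:
        paths["cvr_adjusted"] = save_map(res.cvr_adjusted, out / "cvr_adjusted.nii")
        paths["r2_adjusted"] = save_map(res.r2_adjusted, out / "r2_adjusted.nii")
    write_regressor(res.regressor.trace.times, res.regressor.trace.values,
                    out / "regressor.tsv")
    write_json({"summaries": [s.to_dict() for s in res.summaries],
                "alignment_shift_s": res.alignment_shift_s,
                "alignment_r": res.alignment_r}, out / "summary.json")
    for s in res.summaries:
        name = f"hist_{s.tissue.lower()}_{s.parameter.lower()}.tsv"
        pd.DataFrame({"bin_edge": np.asarray(s.bin_edges)[1:],
                      "cumulative_pct": s.cumulative_pct}).to_csv(
            out / name, sep="\t", index=False, float_format="%.10g")

    manifest = {
        "cvrlag_version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "inputs": {name: {"path": str(p), "sha256": _sha256(p)}
                   for name, p in (("bold", cfg.bold_path),
                                   ("trace", cfg.trace_path),
                                   ("gm_prob", cfg.gm_prob_path),
                                   ("wm_prob", cfg.wm_prob_path))},
        "outputs": {k: str(v) for k, v in paths.items()},
        "alignment_shift_s": res.alignment_shift_s,
        "alignment_r": res.alignment_r,
        "regressor": {"provenance": res.regressor.provenance,
                      "n_voxels_used": res.regressor.n_voxels_used},
    }
    write_json(manifest, out / "manifest.json")
    return manifest
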