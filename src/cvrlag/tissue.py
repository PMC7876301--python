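"""Tissue-level statistics: masks, distributions, group maps, recovery scoring.

Gray- and white-matter regions are obtained by thresholding tissue
probability maps (inclusive convention, prob >= threshold; defaults 50% for
GM and 90% for WM). Per-tissue parameter distributions are summarized as
mean +/- SD and as cumulative percent-frequency histograms normalized to
100%. Group-average maps count only valid per-run entries and invalidate
voxels covered by fewer than a minimum number of runs (default 4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .containers import VoxelMap
from .errors import EmptyRegionError, InvalidSpecError
from .phantom import PhantomTruth

#: Histogram bin defaults: 4 s for lag, 0.05 %/mmHg for CVR.
DEFAULT_LAG_BINS = np.arange(-12.0, 92.0 + 4.0, 4.0)
DEFAULT_CVR_BINS = np.arange(-0.5, 1.5 + 0.05, 0.05)


def binarize_mask(prob: VoxelMap | np.ndarray, threshold_pct: float) -> np.ndarray:
    """Binarize a tissue probability map: voxel in iff prob >= threshold/100."""
    p = prob.data if isinstance(prob, VoxelMap) else np.asarray(prob, float)
    if not 0 < threshold_pct <= 100:
        raise InvalidSpecError("threshold_pct must lie in (0, 100]")
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise InvalidSpecError("probability map values must lie in [0, 1]")
    return p >= threshold_pct / 100.0


@dataclass
class TissueSummary:
    """Distribution summary of one parameter inside one tissue mask."""

    tissue: str
    parameter: str
    mean: float
    sd: float
    n_voxels: int
    bin_edges: np.ndarray
    cumulative_pct: np.ndarray
    bin_pct: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "tissue": self.tissue,
            "parameter": self.parameter,
            "mean": self.mean,
            "sd": self.sd,
            "n_voxels": self.n_voxels,
            "bin_edges": np.asarray(self.bin_edges).tolist(),
            "cumulative_pct": np.asarray(self.cumulative_pct).tolist(),
        }


def tissue_summary(vmap: VoxelMap, mask: np.ndarray,
                   bins: np.ndarray | None = None,
                   tissue: str = "GM", parameter: str = "LAG") -> TissueSummary:
    """Mean, SD (n-1 denominator) and cumulative histogram over a region.

    The cumulative percent frequency is normalized so its last bin reaches
    exactly 100 (values outside the bin range are counted into the nearest
    edge bin first, so no mass is lost).
    """
    mask = np.asarray(mask, bool)
    vals = vmap.valid_values(mask)
    if vals.size == 0:
        raise EmptyRegionError(f"no valid {parameter} voxels in {tissue} mask")
    if bins is None:
        bins = DEFAULT_LAG_BINS if parameter.upper() == "LAG" else DEFAULT_CVR_BINS
    bins = np.asarray(bins, float)
    clipped = np.clip(vals, bins[0], bins[-1])
    counts, _ = np.histogram(clipped, bins)
    bin_pct = 100.0 * counts / counts.sum()
    cum = np.cumsum(bin_pct)
    cum[-1] = 100.0  # exact by construction; pin against round-off
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return TissueSummary(tissue=tissue, parameter=parameter,
                         mean=float(vals.mean()), sd=sd, n_voxels=int(vals.size),
                         bin_edges=bins, cumulative_pct=cum, bin_pct=bin_pct)


def group_average(maps: Sequence[VoxelMap], min_points: int = 4) -> VoxelMap:
    """Voxelwise mean over runs, counting valid entries only.

    Voxels with fewer than ``min_points`` valid contributions are invalid in
    the group map — the minimum-coverage filter applied to group-averaged
    lag/CVR maps.
    """
    if len(maps) == 0:
        raise InvalidSpecError("need at least one map")
    shape = maps[0].shape
    units = maps[0].units
    for m in maps:
        if m.shape != shape:
            raise InvalidSpecError("all maps must share the grid")
    count = np.zeros(shape, dtype=int)
    total = np.zeros(shape, dtype=float)
    for m in maps:
        v = m.valid
        count += v
        total[v] += m.data[v]
    ok = count >= min_points
    out = np.full(shape, np.nan)
    out[ok] = total[ok] / count[ok]
    return VoxelMap(out, units, ok)


@dataclass
class RecoveryReport:
    """Bias/RMSE of estimated maps against phantom ground truth."""

    entries: dict
    seed: int | None = None
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"entries": self.entries, "seed": self.seed, "config": self.config}


def recovery_report(estimated: Mapping[str, VoxelMap], truth: PhantomTruth,
                    masks: Mapping[str, np.ndarray],
                    lag_offset_s: float = 0.0,
                    seed: int | None = None) -> RecoveryReport:
    """Score estimated lag/CVR maps against the phantom truth per tissue.

    ``estimated`` maps keyed by parameter ("lag", "cvr"); ``masks`` keyed by
    tissue name. ``lag_offset_s`` is added to the estimated lags before
    comparison, to move them from the aligned-trace timeline back onto the
    stimulus timeline the truth is defined on.
    """
    truth_maps = {"lag": truth.true_lag, "cvr": truth.true_cvr}
    entries: dict[str, dict] = {}
    for pname, est in estimated.items():
        if pname not in truth_maps:
            raise InvalidSpecError(f"no ground truth for parameter {pname!r}")
        tmap = truth_maps[pname]
        if est.shape != tmap.shape:
            raise InvalidSpecError("estimated and truth grids differ")
        offset = lag_offset_s if pname == "lag" else 0.0
        for tname, mask in masks.items():
            sel = est.valid & tmap.valid & np.asarray(mask, bool)
            n = int(sel.sum())
            if n == 0:
                entries[f"{tname}.{pname}"] = {"bias": np.nan, "rmse": np.nan, "n": 0}
                continue
            err = (est.data[sel] + offset) - tmap.data[sel]
            entries[f"{tname}.{pname}"] = {
                "bias": float(err.mean()),
                "rmse": float(np.sqrt(np.mean(err**2))),
                "n": n,
            }
    return RecoveryReport(entries=entries, seed=seed)


def plot_cumulative_histograms(summaries: Sequence[TissueSummary], path,
                               reference_s: float = 40.0) -> None:
    """Optional figure: per-tissue cumulative lag histograms with a reference
    line (requires matplotlib, which is not a core dependency)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    shades = {"GM": "black", "WM": "gray"}
    for s in summaries:
        centers = 0.5 * (np.asarray(s.bin_edges)[:-1] + np.asarray(s.bin_edges)[1:])
        ax.plot(centers, s.cumulative_pct, color=shades.get(s.tissue, None),
                label=f"{s.tissue} {s.parameter}")
    ax.axvline(reference_s, color="red", linestyle=":")
    ax.set_xlabel(summaries[0].parameter.lower())
    ax.set_ylabel("cumulative percent frequency")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
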