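"""Shared in-memory containers for the mapping pipeline.

The pipeline moves three kinds of objects between stages: 4D BOLD images on a
repetition-time (TR) clock, uniformly sampled reference traces (end-tidal CO2
excursions, probe/optimized regressors), and 3D scalar maps (lag in seconds,
CVR in %BOLD/mmHg, correlation coefficients) with an explicit validity mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, InvalidSpecError

#: Allowed unit tags for :class:`VoxelMap`.
MAP_UNITS = ("seconds", "pct_per_mmHg", "r", "r2", "dimensionless", "label")


@dataclass
class BoldImage4D:
    """A 4D BOLD time series: voxel grid x time, with its repetition time.

    Parameters
    ----------
    data:
        Array of shape ``(nx, ny, nz, nt)`` in arbitrary scanner units.
    tr_s:
        Time between volumes in seconds (the analysis also uses this class for
        oversampled data, where ``tr_s`` is the fine grid step).
    affine:
        4x4 voxel-to-world transform, carried through to outputs unchanged.
    """

    data: np.ndarray
    tr_s: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise InvalidSpecError("BOLD data must be 4D (nx, ny, nz, nt)")
        if self.data.shape[3] < 16:
            raise InvalidSpecError("BOLD series needs at least 16 time points")
        if not np.all(np.isfinite(self.data)):
            raise InvalidSpecError("BOLD data contains non-finite values")
        if not self.tr_s > 0:
            raise InvalidSpecError("tr_s must be positive")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def nt(self) -> int:
        return self.data.shape[3]

    @property
    def times(self) -> np.ndarray:
        """Acquisition times of each volume, seconds from scan start."""
        return np.arange(self.nt) * self.tr_s


@dataclass
class UniformTrace:
    """A uniformly sampled time course on the BOLD clock.

    ``t0_s`` is the time of the first sample relative to scan start; it is
    nonzero e.g. for an optimized regressor defined only on the common support
    of its contributing voxels.
    """

    values: np.ndarray
    dt_s: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InvalidSpecError("trace values must be 1D")
        if not self.dt_s > 0:
            raise InvalidSpecError("dt_s must be positive")
        if not np.all(np.isfinite(self.values)):
            raise InvalidSpecError("trace contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.values)) * self.dt_s


@dataclass
class VoxelMap:
    """A 3D scalar map with a per-voxel validity mask.

    ``data`` may hold NaN outside ``valid``; it must be finite wherever
    ``valid`` is set.
    """

    data: np.ndarray
    units: str
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.data.ndim != 3:
            raise InvalidSpecError("VoxelMap data must be 3D")
        if self.valid.shape != self.data.shape:
            raise InvalidSpecError("valid mask shape must match data shape")
        if self.units not in MAP_UNITS:
            raise InvalidSpecError(f"unknown map units {self.units!r}")
        if not np.all(np.isfinite(self.data[self.valid])):
            raise InvalidSpecError("VoxelMap has non-finite values flagged valid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def valid_values(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Values at valid voxels, optionally restricted to ``mask``."""
        sel = self.valid if mask is None else (self.valid & np.asarray(mask, bool))
        return self.data[sel]


def zscore(x: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance normalization (population SD)."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise DegenerateInputError("cannot z-score a zero-variance series")
    return (x - x.mean()) / sd


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two equal-length 1D arrays."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise DegenerateInputError("Pearson correlation of a constant series")
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))
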