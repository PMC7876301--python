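"""Exception types shared across the pipeline stages."""


class CvrlagError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(CvrlagError, ValueError):
    """A paradigm/phantom/analysis specification violates its invariants."""


class TraceFormatError(CvrlagError, ValueError):
    """An end-tidal trace file is malformed (bad header, non-monotonic times...)."""


class DegenerateInputError(CvrlagError, ValueError):
    """An input has no usable variance (all-constant signal, empty region...)."""


class ExtrapolationError(CvrlagError, ValueError):
    """A resampling grid extends beyond the support of the source trace."""


class RefinementError(CvrlagError, RuntimeError):
    """Regressor refinement failed (no voxel passed the correlation threshold)."""


class EmptyRegionError(CvrlagError, ValueError):
    """A mask/valid intersection contains no voxels."""
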