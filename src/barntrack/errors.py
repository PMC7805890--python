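"""Exception types shared across the package."""


class BarntrackError(Exception):
    """Base class for barntrack-specific errors."""


class DataError(BarntrackError):
    """Input data violates its documented contract (values, columns, ids)."""


class SequencingError(BarntrackError):
    """Frames or events were supplied out of order."""


class GeometryError(BarntrackError):
    """Degenerate geometric configuration (rank-deficient correspondences)."""


class ConvergenceError(BarntrackError):
    """An iterative numerical routine failed to converge."""
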