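"""Exception hierarchy for phasete.

All package-specific failures derive from :class:`PhaseteError` so callers can
catch one base class at pipeline boundaries.
"""


class PhaseteError(Exception):
    """Base class for all phasete errors."""


class InvalidBandError(PhaseteError, ValueError):
    """Requested pass band lies outside (0, Nyquist) or is not ordered."""


class InsufficientSamplesError(PhaseteError, ValueError):
    """Too few samples for the requested operation (filter order, embedding, k-NN)."""


class ShapeError(PhaseteError, ValueError):
    """Trial matrices are ragged or shapes are inconsistent."""


class MetadataError(PhaseteError, KeyError):
    """Required metadata (e.g. sampling rate) missing from a container."""


class DegenerateSignalError(PhaseteError, ValueError):
    """A trial has zero variance where variance is required."""


class DegenerateDistributionError(PhaseteError, ValueError):
    """Circular dispersion is zero or undefined; no bin width can be derived."""


class UndefinedDispersionError(DegenerateDistributionError):
    """Mean resultant length is zero: circular standard deviation undefined."""


class NoValidEmbeddingError(PhaseteError, ValueError):
    """No (d, tau) candidate leaves a positive number of embedded rows."""


class SimulationFailureError(PhaseteError, RuntimeError):
    """Neural-mass integration produced non-finite state."""


class MemoryGuardError(PhaseteError, MemoryError):
    """Sample count exceeds the Gram-matrix guard of the kernel estimator."""


class CannotShuffleError(PhaseteError, ValueError):
    """Trial shuffling needs at least two trials."""


class EmptySelectionError(PhaseteError, ValueError):
    """Epoch quality control rejected every epoch."""


class ConfigurationError(PhaseteError, ValueError):
    """Inconsistent user configuration (off-grid lag, empty grid, ...)."""
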