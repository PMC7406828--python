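"""Exception types shared across the pipeline."""


class ExpmseError(Exception):
    """Base class for all package errors."""


class ConfigError(ExpmseError):
    """Invalid configuration or effect specification."""


class DecompositionError(ExpmseError):
    """EEMD failed or produced too few intrinsic mode functions."""


class UndefinedEntropyError(ExpmseError):
    """An entropy statistic has no defined points (no template matches)."""


class ContainerError(ExpmseError):
    """Missing or incompatible datasets in an HDF5 subject container."""
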