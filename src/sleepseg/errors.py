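"""Exception hierarchy shared across the package.

Everything derives from :class:`SleepsegError` so callers (and the CLI) can
catch package failures with a single ``except`` clause while still getting a
specific class for programmatic handling.
"""


class SleepsegError(Exception):
    """Base class for all sleepseg errors."""


class FormatError(SleepsegError):
    """A file could not be parsed under the requested dialect, or its channel
    inventory does not match the canonical montage."""


class AlignmentError(SleepsegError):
    """Signals and an annotation track disagree in length."""


class ValidationError(SleepsegError, ValueError):
    """A value violates a domain contract (e.g. probability outside [0, 1])."""


class ParameterError(SleepsegError, ValueError):
    """A function argument is out of its allowed range."""


class ShapeError(SleepsegError, ValueError):
    """Array dimensions are inconsistent with what an operation requires."""


class SizeError(SleepsegError, ValueError):
    """A target size is incompatible with the input size (e.g. padding that
    would truncate)."""


class ConfigError(SleepsegError, ValueError):
    """A configuration object violates its invariants."""


class UndefinedMetricError(SleepsegError):
    """A metric or loss is undefined on the given labels (e.g. no scored
    samples, or a single-class label set for AUROC)."""


class PairingError(SleepsegError):
    """Label and prediction collections could not be matched by record id."""


class PlacementError(SleepsegError):
    """Synthetic events could not be placed without overlap."""
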