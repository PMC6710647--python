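"""Exception types shared across locuskit modules."""


class LocuskitError(ValueError):
    """Base class for all locuskit input/consistency errors."""


class LayoutError(LocuskitError):
    """Two placed features overlap or a feature falls outside the genome."""


class UnsupportedEventError(LocuskitError):
    """Requested recombination event is outside the supported model
    (e.g. opposite-strand NAHR, which would form an inversion)."""


class InputError(LocuskitError):
    """Malformed sequence or table input."""


class RegionError(LocuskitError):
    """A labelled region lies outside the coordinate span it refers to."""


class CoverageError(LocuskitError):
    """Hybrid sequence covers too few discriminating-site positions to classify."""


class NoSignalError(LocuskitError):
    """No parentally-assignable site remains, so no breakpoint can be bounded."""


class FrameError(LocuskitError):
    """Coding sequence length is not a multiple of three."""


class ReferenceFailureError(LocuskitError):
    """Digital-PCR reference channel detected no molecules."""


class SaturationError(LocuskitError):
    """All digital-PCR partitions positive; concentration not estimable."""
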