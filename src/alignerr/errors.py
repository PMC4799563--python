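"""Exception hierarchy shared across the package."""


class AlignerrError(Exception):
    """Base class for all package errors."""


class MsaFormatError(AlignerrError):
    """Malformed alignment or tree input (unequal rows, bad characters, ...)."""


class InputError(AlignerrError):
    """Semantically invalid input (e.g. two MSAs of different sequences)."""


class DomainError(AlignerrError):
    """An operation was called outside its domain of definition."""


class CapabilityError(AlignerrError):
    """A requested error injection is not supported for the chosen target."""


class SimulationError(AlignerrError):
    """The stochastic simulation reached an unusable state (e.g. empty sequence)."""


class IntractableSegmentError(AlignerrError):
    """A gapped segment exceeded the enumeration caps.

    Carries the partial result so callers can exclude the segment and go on,
    mirroring the screening of overlong segments in large-scale runs.
    """

    def __init__(self, message, partial=None):
        super().__init__(message)
        self.partial = partial
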