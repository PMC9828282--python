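"""Exception hierarchy for the pipeline."""


class MultiplexPSNError(Exception):
    """Base class for all package errors."""


class FormatError(MultiplexPSNError, ValueError):
    """Malformed input file (non-square matrix, duplicate labels, ...)."""


class DomainError(MultiplexPSNError, ValueError):
    """A value lies outside its allowed domain (e.g. identity not in [0, 100])."""


class AlignmentError(MultiplexPSNError, ValueError):
    """Inconsistent multiple sequence alignment (unequal lengths, empty)."""


class InputError(MultiplexPSNError, ValueError):
    """Inconsistent inputs across layers (mismatched organism sets, ...)."""


class SelectionError(MultiplexPSNError, RuntimeError):
    """Automatic threshold / partition selection could not be completed.

    Carries the diagnostic object (e.g. the dissimilarity profile) in
    ``diagnostic`` so callers can inspect why selection failed.
    """

    def __init__(self, message, diagnostic=None):
        super().__init__(message)
        self.diagnostic = diagnostic
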