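"""Package exception hierarchy.

``CorneoramanError`` is the base class for every error the library raises on
purpose; the CLI maps it to exit code 1 (user/data error) while anything else
is treated as an internal error (exit code 2).
"""


class CorneoramanError(Exception):
    """Base class for all errors raised by corneoraman."""


class ValidationError(CorneoramanError, ValueError):
    """A domain invariant was violated (bad wavenumber axis, bad window, ...)."""


class MissingDataError(CorneoramanError, FileNotFoundError):
    """An expected file, depth or spectral region is absent."""


class FitError(CorneoramanError, RuntimeError):
    """A fit or landmark-detection step could not produce a result."""
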