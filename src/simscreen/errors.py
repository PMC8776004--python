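"""Exception types raised across the package."""


class SimscreenError(Exception):
    """Base class for all package errors."""


class MoleculeParseError(SimscreenError):
    """Input text could not be parsed into a molecule.

    Carries the offending text in ``.text``.
    """

    def __init__(self, text: str, reason: str = "unparsable input"):
        self.text = text
        self.reason = reason
        super().__init__(f"{reason}: {text!r}")


class EmbeddingError(SimscreenError):
    """3D conformer embedding failed for a record."""


class LengthMismatchError(SimscreenError):
    """Two fingerprints/vectors with incompatible lengths or parameters."""


class SignatureMismatchError(SimscreenError):
    """MinHash signatures built with different k or permutation seeds."""


class EmptyInputError(SimscreenError):
    """An operation received an empty collection it cannot handle."""


class StoreMismatchError(SimscreenError):
    """Query configuration does not match the fingerprint store header."""


class StoreFormatError(SimscreenError):
    """Corrupt or inconsistent fingerprint-store file."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class CalibrationError(SimscreenError):
    """Calibration procedure cannot proceed (e.g. empty bins, no crossing)."""


class SamplingError(SimscreenError):
    """Pair sampling is impossible for the requested sizes."""


class GrammarError(SimscreenError):
    """Synthetic-library fragment grammar cannot satisfy its constraints."""
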