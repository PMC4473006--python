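"""Exception types shared across the package."""

from __future__ import annotations


class OstaiError(Exception):
    """Base class for all package-specific errors."""


class DomainError(OstaiError):
    """A precondition on the clinical/statistical domain was violated.

    Carries an optional ``qc_log`` so callers that excluded every
    participant can still inspect why.
    """

    def __init__(self, message: str, qc_log=None):
        super().__init__(message)
        self.qc_log = qc_log


class SchemaError(OstaiError):
    """An input file does not conform to the documented cohort schema."""
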