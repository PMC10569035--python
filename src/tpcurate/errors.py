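"""Exception hierarchy for the curation pipeline.

Every error raised on a user-facing path derives from :class:`TPCurateError`
so callers (and the CLI) can distinguish pipeline validation failures from
programming errors.
"""

from __future__ import annotations


class TPCurateError(Exception):
    """Base class for all pipeline errors."""


class StructureError(TPCurateError):
    """A structure string could not be parsed or processed.

    Carries the offending input in ``offending``.
    """

    def __init__(self, message: str, offending: str | None = None):
        super().__init__(message)
        self.offending = offending


class SaltStripError(StructureError):
    """Desalting failed, e.g. a multi-component input with no organic part."""


class AnnotationParseError(TPCurateError):
    """The annotation document does not conform to the supported dialect.

    ``path`` names the offending record location inside the document.
    """

    def __init__(self, message: str, path: str = "$"):
        super().__init__(f"{path}: {message}")
        self.path = path


class SpanValidationError(TPCurateError):
    """A markup span is inconsistent with its excerpt text."""

    def __init__(self, message: str, span=None):
        super().__init__(message)
        self.span = span


class SchemaError(TPCurateError):
    """A tabular artifact has missing or unknown columns.

    ``missing`` / ``unknown`` list the offending column names.
    """

    def __init__(self, message: str, missing=(), unknown=()):
        super().__init__(message)
        self.missing = list(missing)
        self.unknown = list(unknown)


class CurationError(TPCurateError):
    """A curation decision cannot be applied to the candidate table."""


class UndecidedError(CurationError):
    """Finalization was attempted while candidates remain undecided."""

    def __init__(self, undecided_ids):
        self.undecided_ids = list(undecided_ids)
        super().__init__(
            f"{len(self.undecided_ids)} candidate(s) have no decision; "
            "pass allow_undecided=True to proceed"
        )


class MergePolicyError(TPCurateError):
    """A merge was attempted that the selected policy forbids."""


class ScreeningError(TPCurateError):
    """A screening-stage computation has no usable input (e.g. no pairs)."""


class FixtureParameterError(TPCurateError):
    """Fixture generator parameters are out of range or inconsistent."""
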