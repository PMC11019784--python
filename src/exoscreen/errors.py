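"""Exception types shared across the pipeline."""


class ExoscreenError(Exception):
    """Base class for all package errors."""


class ValidationError(ExoscreenError):
    """A table or configuration violated its schema or invariants.

    Carries optional file / row / field context so that CLI users can
    locate the offending line in their input.
    """

    def __init__(self, message, *, file=None, row=None, field=None):
        self.file = file
        self.row = row
        self.field = field
        parts = []
        if file is not None:
            parts.append(f"file={file}")
        if row is not None:
            parts.append(f"row={row}")
        if field is not None:
            parts.append(f"field={field}")
        if parts:
            message = f"{message} ({', '.join(parts)})"
        super().__init__(message)


class DesignError(ValidationError):
    """Invalid experimental design (duplicate conditions, missing control...)."""


class MissingReferenceError(ExoscreenError):
    """A required reference sample group is absent from the feature matrix."""


class GroupSizeError(ExoscreenError):
    """A statistical test was asked to run on fewer than two replicates."""
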