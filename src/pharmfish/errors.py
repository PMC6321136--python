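"""Structured error hierarchy; the CLI maps these to distinct exit codes."""


class PharmfishError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class StructureError(PharmfishError):
    """A compound structure could not be parsed or sanitized."""

    exit_code = 3

    def __init__(self, compound_id: str, reason: str):
        self.compound_id = compound_id
        self.reason = reason
        super().__init__(f"malformed structure for compound {compound_id!r}: {reason}")


class SchemaError(PharmfishError):
    """A tabular artifact violated its schema (labels, duplicates, headers)."""

    exit_code = 4


class DegenerateDataError(PharmfishError):
    """Dataset too small or too uniform for the requested operation."""

    exit_code = 5
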