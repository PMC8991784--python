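"""Exception types shared across the pipeline."""


class PhysnetError(Exception):
    """Base class for all package errors."""


class ConfigError(PhysnetError):
    """Invalid or unknown configuration value; the message names the field."""


class ValidationError(PhysnetError):
    """Input data violates a schema or referential invariant.

    ``rows`` holds (row index, reason) diagnostics for the offending rows
    (capped for readability).
    """

    def __init__(self, message: str, rows: list[tuple[int, str]] | None = None):
        self.rows = rows or []
        if self.rows:
            shown = "; ".join(f"row {i}: {why}" for i, why in self.rows[:10])
            more = "" if len(self.rows) <= 10 else f" (+{len(self.rows) - 10} more)"
            message = f"{message}: {shown}{more}"
        super().__init__(message)
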