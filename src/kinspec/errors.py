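"""Error taxonomy.

Every failure mode raised by the library carries a short machine-readable
``code`` so callers (and the CLI) can branch on the cause without parsing
messages.
"""

from __future__ import annotations


class KinspecError(ValueError):
    """Base class for all domain errors; ``code`` is a stable identifier."""

    def __init__(self, code: str, message: str):
        self.code = code
        super().__init__(f"{code}: {message}")


class DataError(KinspecError):
    """Malformed or insufficient input data (CLI exit code 2)."""


class ComputationError(KinspecError):
    """A computation could not be carried out on valid-looking data (exit 3)."""
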