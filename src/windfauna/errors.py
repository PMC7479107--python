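"""Exception hierarchy shared across the package.

Every error raised by the scoring pipeline derives from :class:`WindfaunaError`
so callers (and the CLI) can distinguish domain failures from programming
errors. Validation errors carry a short machine-readable ``code`` in addition
to the human-readable message.
"""

from __future__ import annotations


class WindfaunaError(Exception):
    """Base class for all package errors."""


class GeometryError(WindfaunaError, ValueError):
    """Turbine or farm geometry is physically impossible (e.g. tower not
    taller than the blades, zero frontal area)."""


class DomainError(WindfaunaError, ValueError):
    """A numeric input lies outside the domain a formula is defined on."""


class ValidationError(WindfaunaError, ValueError):
    """An input document or table failed schema validation.

    Parameters
    ----------
    message:
        Human-readable description; includes field paths and, for files,
        line or row references.
    code:
        Stable machine-readable identifier, e.g. ``missing-field``,
        ``invalid-value``, ``negative-distance``, ``duplicate-species``.
    """

    def __init__(self, message: str, code: str = "invalid-value"):
        super().__init__(message)
        self.code = code
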