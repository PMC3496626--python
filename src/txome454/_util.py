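"""Small shared helpers: exact percent arithmetic and error types."""

from __future__ import annotations


class ValidationError(ValueError):
    """Input violates a documented invariant."""


class ConfigError(ValueError):
    """A configuration field is outside its documented domain."""


class ParseError(ValueError):
    """Malformed input file; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def truncate_ratio_percent(num: int, den: int, digits: int = 2) -> float:
    """Percent 100*num/den truncated (not rounded) to ``digits`` decimals.

    Integer arithmetic throughout, so e.g. 1935/2579 -> 75.02 exactly
    rather than 75.03; truncation is the reporting convention used for
    all fractional coverage/rate percentages in this package.
    """
    if den <= 0:
        raise ValidationError("denominator must be positive")
    scale = 10**digits
    return (100 * scale * num // den) / scale


def truncate_ratio(num: int, den: int, digits: int = 2) -> float:
    """num/den truncated to ``digits`` decimals (e.g. 6931/4314 -> 1.60)."""
    if den <= 0:
        raise ValidationError("denominator must be positive")
    scale = 10**digits
    return (scale * num // den) / scale


def round_ratio_percent(num: int, den: int) -> int:
    """Percent rounded to the nearest integer (half away from zero)."""
    if den <= 0:
        raise ValidationError("denominator must be positive")
    return int((200 * num + den) // (2 * den))
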