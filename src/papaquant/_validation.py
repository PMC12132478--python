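"""Small parameter-validation helpers shared across modules.

All validators raise :class:`ValidationError` naming the offending field so
that configuration mistakes surface with an actionable message.
"""

from __future__ import annotations

import math


class ValidationError(ValueError):
    """A named parameter failed validation."""


def check_finite(name: str, value: float) -> float:
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    return value


def check_prob(name: str, value: float) -> float:
    check_finite(name, value)
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must be a probability in [0, 1], got {value!r}")
    return value


def check_nonneg(name: str, value: float) -> float:
    check_finite(name, value)
    if value < 0:
        raise ValidationError(f"{name} must be >= 0, got {value!r}")
    return value


def check_pos(name: str, value: float) -> float:
    check_finite(name, value)
    if value <= 0:
        raise ValidationError(f"{name} must be > 0, got {value!r}")
    return value


def check_int_min(name: str, value: int, minimum: int) -> int:
    if int(value) != value:
        raise ValidationError(f"{name} must be an integer, got {value!r}")
    if value < minimum:
        raise ValidationError(f"{name} must be >= {minimum}, got {value!r}")
    return int(value)
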