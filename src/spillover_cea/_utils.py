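"""Small shared numeric helpers."""

from __future__ import annotations

import math


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round with halves going away from zero (153.5 -> 154, -153.5 -> -154).

    Python's built-in ``round`` uses banker's rounding; reported tables here
    follow the commercial convention instead, applied at the reporting layer
    only.
    """
    if not math.isfinite(value):
        raise ValueError(f"cannot round non-finite value {value!r}")
    factor = 10.0**ndigits
    scaled = abs(value) * factor
    # guard against representation droop just below an exact half
    rounded = math.floor(scaled + 0.5 + 1e-12)
    return math.copysign(rounded / factor, value)


def check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value
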