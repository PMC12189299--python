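"""Small shared helpers."""

from __future__ import annotations

import math

import numpy as np


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used for printed coefficients
    and percent values, as opposed to Python's banker's rounding)."""
    if not math.isfinite(x):
        return x
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def as_float_array(values, name: str = "values") -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr
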