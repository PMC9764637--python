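"""Small shared helpers."""

from __future__ import annotations

import math

import numpy as np


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero toward +inf.

    This is the reporting convention used for risk-score thresholds and
    percentages (e.g. 57.77 -> 58, 21.5 -> 22); Python's built-in ``round``
    uses banker's rounding and would give 21.5 -> 21.
    """
    return int(math.floor(float(x) + 0.5))


def check_positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be a positive finite number, got {value!r}")


def check_nonnegative(name: str, value: float) -> None:
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be a non-negative finite number, got {value!r}")


def as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    return arr


def derive_seed(seed: int, stream: int) -> int:
    """Derive an independent child seed below 2**31 from a master seed."""
    ss = np.random.SeedSequence([int(seed), int(stream)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
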