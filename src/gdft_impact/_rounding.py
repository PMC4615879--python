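"""Rounding conventions used throughout the model.

All headline quantities (patient counts, whole-dollar savings, one-decimal
rates and ratios) round half away from zero, matching the arithmetic of the
published tables they reproduce. Python's built-in ``round`` is banker's
rounding and would differ on exact .5 ties.
"""

import math


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero."""
    if x >= 0:
        return int(math.floor(x + 0.5))
    return -int(math.floor(-x + 0.5))


def round_half_up_to(x: float, ndigits: int) -> float:
    """Round to ``ndigits`` decimal places, ties away from zero."""
    factor = 10.0 ** ndigits
    return round_half_up(x * factor) / factor
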