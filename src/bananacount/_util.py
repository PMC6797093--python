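"""Small numeric helpers shared across modules."""

from __future__ import annotations

import numpy as np


def round_half_away(x):
    """Round to nearest integer, ties away from zero.

    numpy's ``round`` rounds half to even; all 8-bit quantization in this
    package commits to half-away-from-zero so examples are bit-stable.
    """
    x = np.asarray(x)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def minmax_unit(a: np.ndarray) -> np.ndarray | None:
    """Min-max normalize to [0, 1]; None when the array is constant."""
    a = np.asarray(a, dtype=float)
    lo, hi = a.min(), a.max()
    if hi == lo:
        return None
    return (a - lo) / (hi - lo)
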