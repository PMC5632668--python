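"""Independent brute-force reference implementations used by the tests.

These deliberately mirror the definitions as literal double loops and stay
independent of the vectorized package code they check.
"""

import math

import numpy as np


def ce_map_bruteforce(values: np.ndarray, sigma: float, radius: int, variant: str = "rms") -> np.ndarray:
    """Literal double-sum local contrast energy (renormalised at borders)."""
    h, w = values.shape
    out = np.zeros((h, w))
    for cy in range(h):
        for cx in range(w):
            wsum = 0.0
            mean = 0.0
            pts = []
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    y, x = cy + dy, cx + dx
                    if 0 <= y < h and 0 <= x < w:
                        wgt = math.exp(-(dx * dx + dy * dy) / (2.0 * sigma * sigma))
                        pts.append((wgt, float(values[y, x])))
                        wsum += wgt
                        mean += wgt * float(values[y, x])
            mean /= wsum
            var = sum(wgt * (v - mean) ** 2 for wgt, v in pts) / wsum
            out[cy, cx] = math.sqrt(var) / mean if variant == "rms" else var / mean**2
    return out


def ecdf_count(sample: np.ndarray, t: float) -> float:
    """F(t) by explicit counting."""
    return sum(1 for x in sample if x <= t) / len(sample)
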