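"""Small shared numerics."""

from __future__ import annotations

import numpy as np


def abs_flat_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """|Pearson r| between two arrays flattened to vectors.

    Returns 0.0 when either side is constant (correlation undefined).
    """
    x = np.asarray(a, dtype=float).ravel()
    y = np.asarray(b, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return 0.0
    return float(min(abs(xc @ yc) / denom, 1.0))
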