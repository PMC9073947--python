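"""Fold-error metrics for predicted vs observed concentration ratios.

AFE (average fold error) is the geometric mean of predicted/observed and
measures scale bias: AFE = 1 means the predictions are centred on the
observations. AAFE (absolute average fold error) takes the absolute value of
each log fold error before averaging, so over- and under-predictions cannot
cancel; AAFE >= 1 always, with equality only at perfect pointwise agreement.
"""

from __future__ import annotations

import numpy as np

__all__ = ["afe", "aafe"]


def _validated(predicted, observed) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    if p.size == 0:
        raise ValueError("fold-error metrics require at least one value")
    if np.any(p <= 0) or np.any(o <= 0):
        raise ValueError("fold-error metrics require strictly positive values")
    return p, o


def afe(predicted, observed) -> float:
    """Signed average fold error, 10**mean(log10(pred/obs))."""
    p, o = _validated(predicted, observed)
    return float(10 ** np.mean(np.log10(p / o)))


def aafe(predicted, observed) -> float:
    """Absolute average fold error, 10**mean(|log10(pred/obs)|)."""
    p, o = _validated(predicted, observed)
    return float(10 ** np.mean(np.abs(np.log10(p / o))))
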