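"""Shared statistical helpers for Monte-Carlo assertions."""
import numpy as np


def se_of_sample_variance(values: np.ndarray) -> float:
    """Standard error of the sample variance, estimated from the sample.

    Var(s^2) ~ (m4 - s^4)/n for large n, with m4 the fourth central moment.
    """
    arr = np.asarray(values, dtype=float)
    n = arr.size
    centred = arr - arr.mean()
    m4 = np.mean(centred**4)
    s2 = np.var(arr)
    return float(np.sqrt(max(m4 - s2**2, 0.0) / n))


def se_of_mean(values: np.ndarray) -> float:
    arr = np.asarray(values, dtype=float)
    return float(arr.std(ddof=1) / np.sqrt(arr.size))


def se_of_proportion(p_hat: float, n: int) -> float:
    return float(np.sqrt(max(p_hat * (1.0 - p_hat), 1e-12) / n))
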