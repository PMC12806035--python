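"""Keyed random-number streams.

One root integer seed drives a whole simulation; every cell (and every
population-level stage) gets its own deterministic child stream keyed by
integers, so the order in which cells happen to divide has no effect on
reproducibility.
"""
from __future__ import annotations

import numpy as np

# stage tags used as the first spawn key
FOUNDER_KEY = 0
DIVIDE_KEY = 1
STEP_KEY = 2
SAMPLE_KEY = 3
SEQ_KEY = 4


def spawn(seed: int, *key: int) -> np.random.Generator:
    """Return a Generator deterministically derived from ``seed`` and ``key``."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)


def as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    """Coerce an int seed (or None) into a numpy Generator; pass Generators through."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit integer seeds from one root seed."""
    state = np.random.SeedSequence(int(seed)).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]
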