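"""Deterministic seed splitting.

Every stochastic draw in the package flows from one integer root seed through
``numpy.random.SeedSequence`` keyed by an explicit tuple of integers (a
counter-based splitting rule): ``substream(seed, *key)`` returns a Generator
whose stream depends only on ``(seed, key)``.  Two consumers with different
keys are statistically independent; the same key always reproduces the same
stream, regardless of the order in which substreams are created.
"""

from __future__ import annotations

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *key: int) -> np.random.Generator:
    """Return an independent ``Generator`` for ``(seed, *key)``.

    Parameters
    ----------
    seed : int
        Root seed (non-negative integer).
    *key : int
        Integer path identifying the consumer, e.g. ``(track_idx, depth_idx,
        component_id)``.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    ss = np.random.SeedSequence([int(seed), *[int(k) & 0xFFFFFFFF for k in key]])
    return np.random.Generator(np.random.PCG64(ss))
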