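"""Seed handling: every stochastic entry point takes a seed or Generator."""

from __future__ import annotations

import numpy as np


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Return a ``numpy.random.Generator`` for an int seed, Generator or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn(seed: int | None, index: int) -> np.random.Generator:
    """Derive an independent child generator from an integer seed.

    Deterministic in (seed, index); used by the pipeline to give each stage
    its own stream without coupling their draw counts.
    """
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(index + 1)[index])
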