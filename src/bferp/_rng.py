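"""Seed plumbing: accept ints, SeedSequences, or Generators uniformly."""

from __future__ import annotations

import numpy as np


def as_seed_sequence(seed) -> np.random.SeedSequence:
    """Wrap ``seed`` in a SeedSequence unless it already is one."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    if isinstance(seed, np.random.Generator):
        # derive a child sequence from the generator's stream
        return np.random.SeedSequence(int(seed.integers(2**31)))
    return np.random.SeedSequence(seed)
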