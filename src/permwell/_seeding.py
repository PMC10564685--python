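"""Deterministic substream derivation from one master seed.

Every source of randomness in the package draws from a substream keyed by
(purpose label, *indices).  Substreams are derived with
``numpy.random.SeedSequence(master_seed, spawn_key=key)``, so the whole
pipeline is reproducible from a single integer and no two purposes ever
share a stream.
"""

from __future__ import annotations

import numpy as np

# Purpose labels used as the first element of the spawn key.
STREAM_PREDICTORS = 0
STREAM_OUTCOME = 1
STREAM_ITEMS = 2
STREAM_SPLIT = 3
STREAM_PERMUTE = 4
STREAM_LEARNER = 5


def child_sequence(master_seed: int, *key: int) -> np.random.SeedSequence:
    """SeedSequence for the substream identified by ``key``."""
    return np.random.SeedSequence(int(master_seed), spawn_key=tuple(int(k) for k in key))


def child_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Generator for the substream identified by ``key``."""
    return np.random.default_rng(child_sequence(master_seed, *key))


def child_int_seed(master_seed: int, *key: int) -> int:
    """A plain int seed (< 2**31) for APIs that take ``random_state`` ints."""
    return int(child_sequence(master_seed, *key).generate_state(1)[0] % (2**31))
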