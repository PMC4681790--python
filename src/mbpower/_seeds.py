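"""Named child random streams derived from one root seed.

Every stochastic stage (community generation, null resamples, power
replicates, CV folds) draws from its own child stream, keyed by stable
string/integer labels, so any stage can be reproduced in isolation and
results do not depend on evaluation order or worker count.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        if key < 0:
            raise ValueError("stream keys must be nonnegative")
        return int(key)
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    raise TypeError(f"stream key must be int or str, got {type(key).__name__}")


def child_rng(root_seed: int, *keys) -> np.random.Generator:
    """Generator for the child stream named by ``keys`` under ``root_seed``."""
    return np.random.default_rng([int(root_seed)] + [_key_to_int(k) for k in keys])


def child_seed(root_seed: int, *keys) -> int:
    """A plain integer seed (< 2**31) for libraries that want one."""
    return int(child_rng(root_seed, *keys).integers(0, 2**31 - 1))
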