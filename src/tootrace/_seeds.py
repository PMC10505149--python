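"""Deterministic seed derivation.

All randomness in the package flows from a single master seed through
named streams, so adding a new random step (or reordering grid combos)
never perturbs existing results.
"""

from __future__ import annotations

import zlib

import numpy as np

MAX_SEED = 2**31 - 1


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """A Generator for the named stream derived from ``seed``.

    Distinct names yield statistically independent streams; the same
    (seed, name) pair always yields the same stream.
    """
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    return np.random.default_rng(ss)


def derive_seed(seed: int, name: str) -> int:
    """A stable integer seed in [0, 2**31) for the named sub-task."""
    return int(stream_rng(seed, name).integers(0, MAX_SEED))
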