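"""Deterministic seed derivation.

All randomness in the package flows from one integer seed.  Independent
streams are derived with :class:`numpy.random.SeedSequence` spawn keys so
that any component (a group's graph, a subject's time series, a
repetition's subsample) can be regenerated on its own without replaying
the whole pipeline.  String keys are mapped to integers with CRC32,
which is stable across platforms and Python processes.
"""

from __future__ import annotations

import zlib

import numpy as np


def _as_int(key: int | str) -> int:
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    return int(key)


def child_seed_sequence(seed: int, *keys: int | str) -> np.random.SeedSequence:
    """A seed sequence for stream ``keys`` under the master ``seed``."""
    return np.random.SeedSequence(int(seed), spawn_key=tuple(_as_int(k) for k in keys))


def child_rng(seed: int, *keys: int | str) -> np.random.Generator:
    """A generator for the independent stream identified by ``keys``."""
    return np.random.default_rng(child_seed_sequence(seed, *keys))


def child_int_seed(seed: int, *keys: int | str) -> int:
    """A plain integer sub-seed (< 2**31) for libraries that want one."""
    return int(child_seed_sequence(seed, *keys).generate_state(1)[0] % (2**31))
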