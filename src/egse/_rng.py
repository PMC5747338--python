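"""Deterministic random-stream derivation.

All stochastic components (permutation tests, rotations, simulators) draw from
independent substreams derived from one master seed plus a string key such as
``(method, collection, contrast, set)``.  Streams therefore do not depend on
scheduling or worker count: consuming them in any order yields identical
results.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng", "derive_seed"]


def derive_seed(master_seed: int, *keys: str | int) -> int:
    """A 31-bit child seed keyed by the master seed and a label path."""
    label = "/".join(str(k) for k in keys)
    return (int(master_seed) ^ zlib.crc32(label.encode("utf-8"))) % (2 ** 31)


def derive_rng(master_seed: int, *keys: str | int) -> np.random.Generator:
    ss = np.random.SeedSequence(
        entropy=int(master_seed) % (2 ** 31),
        spawn_key=tuple(zlib.crc32(str(k).encode("utf-8")) for k in keys),
    )
    return np.random.Generator(np.random.PCG64(ss))
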