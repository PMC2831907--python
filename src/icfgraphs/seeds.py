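"""Deterministic fan-out of a single master seed into per-stage sub-seeds.

Every stochastic stage (imputation replicate, bootstrap replicate, CI test,
simulation) receives ``child_seed(master, *key)`` where ``key`` names the
stage and its indices, e.g. ``child_seed(7, "boot", i, b)``.  The derivation
hashes the key parts with CRC-32 and feeds them with the master seed into a
``numpy.random.SeedSequence``, so replicates are independently reproducible
in any execution order.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_seed(master: int, *key) -> int:
    """A 31-bit sub-seed, a pure function of ``master`` and the key parts."""
    parts = [int(master) & 0xFFFFFFFF]
    parts += [zlib.crc32(repr(k).encode()) for k in key]
    return int(np.random.SeedSequence(parts).generate_state(1)[0] % (2**31))
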