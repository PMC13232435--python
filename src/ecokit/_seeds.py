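"""Deterministic derivation of per-stage child seeds from one global seed.

Every stage of the pipeline draws its randomness from a child seed obtained
by hashing the stage name into a 32-bit offset added to the global seed.
Re-running a single stage in isolation therefore reproduces exactly what the
full pipeline would have done for that stage.
"""

from __future__ import annotations

import zlib

_MOD = 2**31


def child_seed(seed: int, stage: str) -> int:
    """Derive the child seed for ``stage`` from the global ``seed``.

    The derivation is ``(seed + crc32(stage)) mod 2**31`` — stable across
    platforms and Python versions (crc32 is part of the zlib spec).
    """
    return (int(seed) + zlib.crc32(stage.encode("utf-8"))) % _MOD


def iter_seed(seed: int, stage: str, index: int) -> int:
    """Child seed for the ``index``-th repetition inside a stage."""
    return (child_seed(seed, stage) + 0x9E3779B1 * int(index)) % _MOD
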