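"""Deterministic fan-out of one global seed into per-role seeds.

Every stochastic step (fold shuffling, resampling, wrapper CV) draws its
seed from ``derive_seed(base, role)`` with a unique role string, so module
results are reproducible independently of pipeline ordering.
"""

from __future__ import annotations

import zlib


def derive_seed(base: int, role: str) -> int:
    """Stable sub-seed for a named role, in [0, 2^31)."""
    return (int(base) * 1_000_003 + zlib.crc32(role.encode("utf-8"))) % (2**31)
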