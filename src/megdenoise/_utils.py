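"""Small shared helpers."""

from __future__ import annotations

import zlib


def derive_seed(seed: int, label: str) -> int:
    """Deterministic per-stage seed derived from a global seed and a label.

    Keeps every stochastic stage independently reproducible from one global
    seed without re-using streams across stages.  Result is < 2**31.
    """
    return (int(seed) * 1_000_003 + zlib.crc32(label.encode())) % (2**31 - 1)
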