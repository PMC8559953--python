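"""Small shared helpers."""

from __future__ import annotations

import hashlib

__all__ = ["stable_seed"]


def stable_seed(*parts) -> int:
    """Deterministic 63-bit seed from arbitrary repr-able parts.

    Unlike :func:`hash`, the result is stable across processes and runs.
    """
    digest = hashlib.sha256("\x1f".join(map(repr, parts)).encode()).digest()
    return int.from_bytes(digest[:8], "little") & 0x7FFFFFFFFFFFFFFF
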