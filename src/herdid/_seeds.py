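"""Deterministic seed derivation.

Every source of randomness in the package draws from a seed derived from a
single master seed plus a string/int key path, so that no component depends
on global RNG state and any sub-computation can be reproduced in isolation.
"""

from __future__ import annotations

import hashlib

_MOD = 2**31  # keep derived seeds comfortably inside int32 range


def derive_seed(*parts: int | float | str) -> int:
    """Hash a key path of ints/floats/strings into a 31-bit seed.

    Stable across processes and platforms (sha256, not Python ``hash``).
    """
    token = "\x1f".join(_stable(p) for p in parts)
    digest = hashlib.sha256(token.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") % _MOD


def _stable(part: int | float | str) -> str:
    if isinstance(part, bool):  # bool is an int subclass; make it explicit
        return f"b:{int(part)}"
    if isinstance(part, int):
        return f"i:{part}"
    if isinstance(part, float):
        return f"f:{part!r}"
    return f"s:{part}"
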