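"""Shared helpers: seed derivation and validation errors."""

from __future__ import annotations

import hashlib


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


def derive_seed(global_seed: int, component: str) -> int:
    """Derive a component-local seed from a global seed.

    Hash-based so that adding or reordering components never perturbs the
    streams of the others. Result fits in 31 bits.
    """
    digest = hashlib.sha256(f"{global_seed}:{component}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
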