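"""Deterministic seed fan-out.

A single master seed derives one child seed per pipeline stage by hashing the
stage name, so any stage can be re-run in isolation and still see the same
stream it saw inside the full pipeline.
"""

from __future__ import annotations

import hashlib

__all__ = ["child_seed"]


def child_seed(master: int, stage: str) -> int:
    """Derive a stable 31-bit child seed from ``master`` and a stage name."""
    digest = hashlib.sha256(f"{stage}:{int(master)}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
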