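"""Shared small utilities."""
from __future__ import annotations

import hashlib


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from a master seed by hashing the stage name.

    Stages are thereby independently reproducible: re-running one stage with
    the same master seed uses the same stream regardless of what ran before.
    """
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**32)
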