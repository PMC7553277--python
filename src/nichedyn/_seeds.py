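"""Stable seed derivation for stage-level reproducibility.

Stage seeds are derived by hashing the master seed together with stage and
item names, so every emitted number can be reproduced by calling the
underlying operation with the logged seed, and results do not depend on
the order in which species are processed.
"""

from __future__ import annotations

import hashlib

__all__ = ["stable_seed"]


def stable_seed(*parts) -> int:
    """Deterministic 31-bit seed from arbitrary string-able parts."""
    key = "|".join(str(p) for p in parts)
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)
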