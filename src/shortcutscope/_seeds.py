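"""Deterministic seed fan-out.

A single master seed must reproducibly drive every random draw in a run
(splits, weight init, shuffles, per-image perturbation strengths) without
any dependence on iteration order.  Each consumer derives its own child
seed by hashing ``(master_seed, tag)`` with BLAKE2b; tags are stable
strings such as ``"split:3"`` or an image id.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed", "derive_rng"]

_MASK31 = 0x7FFFFFFF  # keep every derived seed a non-negative int32


def derive_seed(master: int, *tags: object) -> int:
    """Derive a child seed from a master seed and any number of tags.

    Deterministic across processes and platforms (no reliance on
    ``hash()``).  Returns an integer in ``[0, 2**31)``.
    """
    key = ":".join([str(int(master))] + [str(t) for t in tags])
    digest = hashlib.blake2b(key.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "big") & _MASK31


def derive_rng(master: int, *tags: object):
    """A ``numpy.random.Generator`` seeded by :func:`derive_seed`."""
    import numpy as np

    return np.random.default_rng(derive_seed(master, *tags))
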