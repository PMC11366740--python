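"""Seed management: one global seed fans out to per-stage streams."""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(seed: int, *tags) -> int:
    """Derive a stable sub-seed (< 2**31) from a root seed and string tags.

    Stages of the pipeline draw from independent streams, so rerunning a
    single stage with the same root seed reproduces it exactly regardless
    of what ran before.
    """
    h = hashlib.blake2b(digest_size=8)
    h.update(str(int(seed)).encode())
    for t in tags:
        h.update(b"/")
        h.update(str(t).encode())
    return int.from_bytes(h.digest(), "little") % (2 ** 31)


def stream(seed: int, *tags) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, *tags))
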