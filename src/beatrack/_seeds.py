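"""Deterministic per-component random streams.

One top-level integer seed is shared by a whole run; every component draws
from its own child stream derived by hashing the component name, so adding
or reordering components never perturbs the streams of the others.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def child_seed(seed: int, name: str) -> np.random.SeedSequence:
    """Child seed sequence for component ``name`` under top-level ``seed``."""
    return np.random.SeedSequence([int(seed), zlib.crc32(name.encode("utf-8"))])


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Generator seeded from :func:`child_seed`."""
    return np.random.default_rng(child_seed(seed, name))
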