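"""Hierarchical seeding.

A single master seed spawns named, order-independent child streams so that
adding a scenario to an experiment never shifts the random numbers consumed
by an existing one, and so that the error-draw streams are shared across
scenarios with the same error SD (common random numbers).
"""

from __future__ import annotations

import zlib

import numpy as np


def child_seed(master_seed: int, *name_parts: object) -> np.random.SeedSequence:
    """Derive a reproducible child ``SeedSequence`` from a master seed and a name.

    The name is any sequence of parts (strings, numbers); it is rendered to a
    canonical string and hashed with CRC-32, so the stream depends only on the
    (master seed, name) pair, never on call order.
    """
    label = ":".join(_canonical(p) for p in name_parts)
    return np.random.SeedSequence([int(master_seed), zlib.crc32(label.encode())])


def child_rng(master_seed: int, *name_parts: object) -> np.random.Generator:
    """A ``numpy`` Generator on the named child stream."""
    return np.random.default_rng(child_seed(master_seed, *name_parts))


def _canonical(part: object) -> str:
    if isinstance(part, float):
        return format(part, "g")
    return str(part)
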