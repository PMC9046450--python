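"""Seed-stream derivation.

Every generator in the package derives an independent child stream from a
single root seed plus a fixed text label, so that adding or reordering
operations never perturbs the draws of another operation.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def child_seed(root_seed: int, label: str) -> np.random.SeedSequence:
    """Derive a named child seed sequence from ``root_seed``.

    The label is hashed with CRC32 so the mapping is stable across runs,
    platforms and Python hash randomisation.
    """
    if root_seed < 0:
        raise ValueError("seed must be non-negative")
    return np.random.SeedSequence(entropy=int(root_seed), spawn_key=(zlib.crc32(label.encode()),))


def child_rng(root_seed: int, label: str) -> np.random.Generator:
    """A ``numpy`` Generator for the (seed, label) stream."""
    return np.random.default_rng(child_seed(root_seed, label))
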