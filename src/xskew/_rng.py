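"""Named, reproducible random substreams.

All randomness in the package flows from a single master seed. Each stage
draws from its own substream so that, e.g., regenerating counts does not
perturb the genotype tables.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *keys: str) -> np.random.Generator:
    """Return a Generator for the substream named by ``keys`` under ``seed``.

    The mapping (seed, keys) -> stream is stable across runs and platforms:
    key strings are hashed with CRC-32 and fed, together with the master
    seed, into a :class:`numpy.random.SeedSequence`.
    """
    entropy = [int(seed)] + [zlib.crc32(k.encode("utf-8")) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
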