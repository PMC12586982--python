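"""Named substreams from a single global seed.

Every simulator derives its generator as ``substream(seed, "name")`` so that
adding a new generator (a new name) never perturbs the draws of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the (seed, name) pair.

    The stream key is a CRC32 of the name, so it is stable across runs,
    platforms and Python hash randomization.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
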