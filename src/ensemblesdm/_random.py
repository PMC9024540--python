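"""Deterministic fan-out of one global seed into named stage sub-seeds."""

from __future__ import annotations

import zlib

import numpy as np


def subseed(seed: int, *tags) -> np.random.Generator:
    """Return a Generator whose stream depends only on ``seed`` and ``tags``.

    Tags are hashed with crc32 so that e.g. ``subseed(s, "fit", "RF", 2)`` is
    stable across runs and independent of call order elsewhere in a pipeline.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy += [zlib.crc32(repr(t).encode("utf-8")) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(entropy))
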