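"""Named, independent PRNG substreams derived from one scene seed."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *names: str) -> np.random.Generator:
    """Return an independent generator keyed by (seed, names).

    The spawn key is derived from stable CRC32 hashes of the names, so the
    mapping name -> stream never depends on call order or Python hashing.
    """
    key = tuple(zlib.crc32(n.encode("utf-8")) for n in names)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))
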