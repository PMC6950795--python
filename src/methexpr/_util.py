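"""Small shared numerics helpers."""

from __future__ import annotations

import zlib

import numpy as np


def logit(p: np.ndarray | float) -> np.ndarray | float:
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


def expit(x: np.ndarray | float) -> np.ndarray | float:
    x = np.asarray(x, dtype=float)
    return 1.0 / (1.0 + np.exp(-x))


def stream_seed(master_seed: int, *tags: str | int) -> np.random.SeedSequence:
    """Named RNG stream derived from a master seed.

    String tags are hashed with crc32 so the stream depends on the name,
    not on the order in which streams are created.
    """
    words = [int(master_seed) & 0x7FFFFFFF]
    for t in tags:
        if isinstance(t, str):
            words.append(zlib.crc32(t.encode("utf-8")))
        else:
            words.append(int(t) & 0xFFFFFFFF)
    return np.random.SeedSequence(words)
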