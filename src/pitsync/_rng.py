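"""Named, independently reproducible random streams.

A single integer seed fans out into named sub-streams (cell layout, response
classes, noise, ...) so that changing how one stream is consumed never
perturbs the others. Stream identity is derived from a CRC32 of the stream
name, which is stable across platforms and Python versions.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the sub-stream `name` of the global `seed`."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((int(seed), key))))
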