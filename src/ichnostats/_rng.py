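"""Named random-number streams.

Each generator draws from its own stream keyed by (seed, stream name), so
adding or reordering generators never shifts the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """Independent Generator for stream *name* under master *seed*."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
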