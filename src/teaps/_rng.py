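"""Named, reproducible random substreams.

A single run seed fans out into independent streams keyed by string labels
(cloud, observation, noise, basin, comparator, ...), so any component can
be replayed in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(seed: int, *labels) -> np.random.Generator:
    """Generator for the substream named by *labels* under *seed*.

    Labels may be strings or integers; the mapping is stable across runs
    and platforms (CRC32 of the label text).
    """
    keys = [zlib.crc32(str(lab).encode()) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, *keys]))
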