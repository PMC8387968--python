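"""Named random substreams derived from one master seed.

Every stage of the pipeline draws from a generator obtained via
:func:`substream`, keyed by a stable string label.  Adding a new stage (or a
new draw inside a stage) therefore never shifts the random numbers any other
stage sees, and a run is fully reproducible from the single master seed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def _key(parts: tuple) -> list[int]:
    return [zlib.crc32(str(p).encode("utf-8")) for p in parts]


def substream_seed(master_seed: int, *names) -> np.random.SeedSequence:
    """SeedSequence for the substream identified by ``names``."""
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *_key(names)])


def substream(master_seed: int, *names) -> np.random.Generator:
    """Independent generator for the substream identified by ``names``."""
    return np.random.default_rng(substream_seed(master_seed, *names))
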