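"""Named random substreams.

All randomness in the package flows from one integer seed. Each logical
stage (reference, truth, counts, reads, spike-ins, assays) draws from its
own substream so that regenerating one stage never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *names: str) -> np.random.Generator:
    """Return a Generator keyed by ``seed`` and a path of stage names.

    Identical (seed, names) always yields an identical stream; distinct
    names yield statistically independent streams.
    """
    key = tuple(zlib.crc32(n.encode("utf-8")) for n in names)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))
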