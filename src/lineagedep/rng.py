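"""Deterministic random-number streams.

One base seed governs a run; every stochastic operation draws from a
stream derived from (seed, label), so adding an operation never perturbs
the draws of the others and fixed-seed runs are bit-reproducible.
"""

from __future__ import annotations

import zlib

import numpy as np


def stream(seed: int, label: str) -> np.random.Generator:
    """A generator keyed by a stable textual label under a base seed."""
    sub = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(sub,)))
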