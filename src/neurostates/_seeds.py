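"""Deterministic seed derivation.

One global seed expands into independent child streams via
``numpy.random.SeedSequence(seed).spawn(...)``; stream order is fixed by the
STREAMS tuple, so the same global seed always yields the same child for a
given stream name.
"""

from __future__ import annotations

import numpy as np

STREAMS = (
    "states",
    "symbols",
    "sensors",
    "lfp",
    "hmm_init",
)


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """Return the RNG for a named child stream of ``seed``."""
    if stream not in STREAMS:
        raise KeyError(f"unknown seed stream {stream!r}; known: {STREAMS}")
    idx = STREAMS.index(stream)
    children = np.random.SeedSequence(seed).spawn(len(STREAMS))
    return np.random.default_rng(children[idx])
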