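"""Named random substreams derived from one global seed."""

from __future__ import annotations

import numpy as np

# Fixed registry so the same name always maps to the same child stream.
_STREAMS = ("split", "init", "batching", "augmentation", "synthesis", "permutation")


def substream(seed: int, name: str) -> np.random.Generator:
    """Return the named child generator of the global ``seed``.

    Components draw from disjoint, reproducible streams: the split plan,
    weight init, batch shuffling, augmentation noise and synthesis never
    share random state, so changing one does not perturb the others.
    """
    if name not in _STREAMS:
        raise KeyError(f"unknown random substream {name!r}; known: {_STREAMS}")
    root = np.random.SeedSequence(int(seed))
    children = root.spawn(len(_STREAMS))
    return np.random.Generator(np.random.PCG64(children[_STREAMS.index(name)]))
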