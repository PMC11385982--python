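"""Seeded random-number streams.

One master seed drives every stochastic step of a run, but each purpose
(mask drawing, Gaussian noise, pool sampling, ...) gets its own derived
stream.  This keeps results bit-reproducible while guaranteeing that,
e.g., enlarging the neighborhood does not reshuffle the noise applied to
samples that were already drawn.
"""

from __future__ import annotations

import numpy as np

# Fixed purpose -> spawn-key registry; append only, never renumber.
_PURPOSES = {
    "masks": 0,
    "epsilon": 1,
    "pool": 2,
    "fixture": 3,
    "augment": 4,
    "table": 5,
    "randomize": 6,
}


def stream(seed: int, purpose: str) -> np.random.Generator:
    """Return the dedicated :class:`numpy.random.Generator` for *purpose*.

    Streams derived from the same master seed are statistically
    independent (distinct ``spawn_key`` on the shared ``SeedSequence``)
    and deterministic across processes and platforms.
    """
    try:
        key = _PURPOSES[purpose]
    except KeyError:
        raise ValueError(f"unknown RNG purpose {purpose!r}") from None
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    return np.random.default_rng(ss)
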