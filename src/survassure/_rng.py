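"""Seed handling: every stochastic routine takes ``rng_seed`` which may be an
int, a Generator, or None (fresh entropy). No global state is used."""

from __future__ import annotations

import numpy as np

SeedLike = "int | np.random.Generator | np.random.SeedSequence | None"


def as_generator(rng_seed=None) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)
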