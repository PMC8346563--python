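"""Small shared helpers: RNG coercion and derived per-stage seeds."""

from __future__ import annotations

import numpy as np

RngLike = "int | np.random.Generator | None"


def as_rng(rng) -> np.random.Generator:
    """Coerce an int seed, Generator, or None into a numpy Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def derive_seed(base_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed (< 2**31) from a global seed.

    A single user-facing seed fans out to independent stage seeds so that
    changing one stage's sampling does not perturb another's.
    """
    h = int(base_seed) & 0xFFFFFFFFFFFFFFFF
    for ch in stage:
        h = ((h * 1099511628211) ^ ord(ch)) & 0xFFFFFFFFFFFFFFFF
    return h % (2**31 - 1)
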