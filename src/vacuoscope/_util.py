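"""Small shared helpers: seeding and validation."""

from __future__ import annotations

import numpy as np

MAX_SEED = 2**31 - 1


def child_seed(master: int, index: int) -> int:
    """Derive a stage/cell seed deterministically from a master seed.

    Counter-based: the same (master, index) pair always yields the same
    child, and distinct indices give statistically independent streams.
    """
    ss = np.random.SeedSequence([int(master), int(index)])
    return int(ss.generate_state(1)[0]) % MAX_SEED


def as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def require(condition: bool, message: str, exc=ValueError) -> None:
    if not condition:
        raise exc(message)
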