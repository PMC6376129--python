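"""Seeding helpers: one independent stream per simulated rat.

Rat i's stream depends only on (master seed, i), so results for a given
rat are invariant to cohort size and execution order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rat_rng", "master_rng"]

_MASK = 0x7FFFFFFF


def master_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(int(seed) & _MASK))


def rat_rng(seed: int, rat_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & _MASK, int(rat_index)])
    )
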