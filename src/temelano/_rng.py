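"""Deterministic random-stream derivation.

One user-facing seed; per-component streams are derived by stable hashing of
(seed, component name) so adding or reordering a pipeline stage never perturbs
the draws of another stage.
"""

from __future__ import annotations

import hashlib

import numpy as np

MAX_SEED = 2**31 - 1


def derive_seed(seed: int, name: str) -> int:
    """Stable 31-bit child seed for component `name` under master `seed`."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & MAX_SEED


def stream(seed: int, name: str) -> np.random.Generator:
    """Independent numpy Generator for one named component."""
    return np.random.default_rng(derive_seed(seed, name))


def choose_index(seed: int, key: str, n: int) -> int:
    """Deterministic uniform choice in [0, n) keyed on (seed, key).

    Used to break equal-score ties per read: stable under reordering or
    parallel execution because the draw depends only on the key, not on how
    many draws happened before.
    """
    if n <= 1:
        return 0
    return derive_seed(seed, "tie:" + key) % n
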