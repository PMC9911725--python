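"""Deterministic seed derivation.

A single master seed is split into independent per-stage seeds by hashing
the stage name, so adding a stage never perturbs the random stream of any
other stage and every output can record the exact seed that produced it.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "rng_for"]


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a stable 31-bit seed for ``stage`` from ``master_seed``."""
    digest = hashlib.sha256(f"{int(master_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def rng_for(master_seed: int, stage: str) -> np.random.Generator:
    """A fresh Generator seeded for one named stage of a run."""
    return np.random.default_rng(derive_seed(master_seed, stage))
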