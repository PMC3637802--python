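"""Deterministic seed fan-out.

One master seed is expanded into independent streams keyed by stage name,
phenotype index, replicate index, etc., so any sub-computation can be redone
in isolation and two runs with the same master seed are bit-identical.
"""

from __future__ import annotations

import zlib

import numpy as np

MAX_SEED = 2**31 - 1


def _key_to_ints(key) -> tuple[int, ...]:
    out = []
    for k in key:
        if isinstance(k, str):
            out.append(zlib.crc32(k.encode("utf-8")))
        else:
            out.append(int(k) & 0xFFFFFFFF)
    return tuple(out)


def seed_sequence(master_seed: int, *key) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=_key_to_ints(key))


def spawn_rng(master_seed: int, *key) -> np.random.Generator:
    """Independent generator for (master seed, hierarchical key)."""
    return np.random.default_rng(seed_sequence(master_seed, *key))


def derive_seed(master_seed: int, *key) -> int:
    """A plain integer seed (< 2**31) derived from the master seed and key."""
    return int(seed_sequence(master_seed, *key).generate_state(1)[0] % MAX_SEED)
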