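"""Deterministic fan-out of one user seed to independent sub-streams.

A single integer seed must drive every random choice in a run (k-means
initialisation for each k, t-SNE, simulation noise) without coupling the
streams: adding or removing one k value must not shift the randomness of
any other.  Each consumer derives its own stream from the root seed plus a
fixed (domain, index) key via numpy's SeedSequence spawn mechanism.
"""

from __future__ import annotations

import zlib

import numpy as np

_DOMAINS = {
    "kmeans": 1,
    "tsne": 2,
    "simulate": 3,
    "shuffle": 4,
    "run": 5,
}


def _domain_code(domain: str) -> int:
    return _DOMAINS.get(domain, zlib.crc32(domain.encode()) & 0x7FFFFFFF)


def derive_rng(seed: int, domain: str, *key: int) -> np.random.Generator:
    """Generator for ``domain`` / ``key`` under root ``seed``."""
    ss = np.random.SeedSequence(int(seed), spawn_key=(_domain_code(domain), *key))
    return np.random.default_rng(ss)


def derive_int_seed(seed: int, domain: str, *key: int) -> int:
    """A 31-bit integer sub-seed (for libraries that take plain ints)."""
    ss = np.random.SeedSequence(int(seed), spawn_key=(_domain_code(domain), *key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
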