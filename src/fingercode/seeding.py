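"""Named, reproducible random streams.

Every stochastic step in the package draws from a generator obtained via
:func:`stream`, so a single master seed determines all outputs while
independent analysis stages (simulation, bootstraps, permutations,
subsampling) never share or race for one generator's state.
"""

from __future__ import annotations

import zlib

import numpy as np


def _name_key(name: str) -> int:
    # stable across processes/platforms, unlike hash()
    return zlib.crc32(name.encode("utf-8"))


def stream(master_seed: int, *names: str | int) -> np.random.Generator:
    """Generator for the stream identified by ``names`` under ``master_seed``."""
    keys = [_name_key(n) if isinstance(n, str) else int(n) for n in names]
    return np.random.default_rng(np.random.SeedSequence(int(master_seed), spawn_key=keys))


def child_seeds(master_seed: int, name: str, n: int) -> list[int]:
    """``n`` integer seeds (< 2**31) derived from one named stream."""
    rng = stream(master_seed, name)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]
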