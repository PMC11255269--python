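"""Named random substreams derived from a single master seed.

Every stochastic routine in the package takes either an integer seed or a
``numpy.random.Generator``.  Pipeline stages derive their generators here so
that one master seed reproduces the whole run while modules stay decoupled.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "as_generator"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The stream is keyed on (seed, crc32(name)) so distinct names give
    statistically independent streams and the mapping is stable across runs
    and platforms.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def as_generator(seed_or_rng: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce an int seed, Generator, or None into a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
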