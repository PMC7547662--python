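"""Seeded random-number streams.

All stochastic operations in the package take an explicit
:class:`numpy.random.Generator`.  A single run seed is expanded into named,
statistically independent substreams ("trials", "observer", "neural", ...)
via :class:`numpy.random.SeedSequence`, so that adding draws to one stage
never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "require_rng"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a named, independent Generator derived from ``seed``.

    The stream name is hashed (CRC-32) into the spawn key so that the same
    (seed, name) pair always yields the same stream.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def require_rng(rng) -> np.random.Generator:
    """Validate that an explicit Generator was passed (no global RNG use)."""
    if not isinstance(rng, np.random.Generator):
        raise TypeError(
            "an explicit numpy.random.Generator is required; "
            "pass e.g. numpy.random.default_rng(seed) or _rng.substream(seed, name)"
        )
    return rng
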