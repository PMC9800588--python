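"""Seed management: one user-facing seed, independent per-stage substreams."""

from __future__ import annotations

import zlib

import numpy as np

MAX_SEED = 2**31 - 1


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return an independent random generator for a named pipeline stage.

    The substream is derived from ``(seed, crc32(stage))`` so that adding or
    reordering stages never perturbs the draws of the others, and the same
    ``(seed, stage)`` pair always reproduces the same stream.
    """
    key = zlib.crc32(stage.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) % MAX_SEED, key]))
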