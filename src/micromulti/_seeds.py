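"""Deterministic per-stage seed derivation.

A single pipeline seed deterministically yields an independent child seed for
every named stage, so stages can be rerun in isolation and still reproduce the
full-pipeline outputs bit for bit.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31 - 1


def derive_seed(seed: int, stage: str) -> int:
    """Derive a stage-specific seed (< 2**31) from a global seed and a stage name."""
    tag = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence([int(seed) % _MOD, tag])
    return int(ss.generate_state(1)[0] % _MOD)
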