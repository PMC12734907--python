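"""Per-stage seed derivation.

Every random draw in a pipeline run descends from a single global seed.
Each named stage gets its own independent stream derived from
``(global_seed, crc32(stage_name))`` via :class:`numpy.random.SeedSequence`,
so results for one stage do not depend on how many draws another stage
consumed, nor on the order in which unrelated stages execute.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_seed", "stage_rng"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a deterministic 31-bit seed for a named pipeline stage."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def stage_rng(global_seed: int, stage: str) -> np.random.Generator:
    """A :class:`numpy.random.Generator` seeded for a named stage."""
    return np.random.default_rng(stage_seed(global_seed, stage))
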