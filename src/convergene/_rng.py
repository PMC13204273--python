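"""Deterministic stream splitting for all stochastic stages.

Every stage draws from its own :class:`numpy.random.Generator` derived from
the single root seed plus a stage label, so any stage can be regenerated
independently of the others and two runs with the same root seed are
bit-identical.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng", "stage_seed"]


def stage_seed(root_seed: int, label: str) -> np.random.SeedSequence:
    """SeedSequence for a named stage under ``root_seed``.

    The label is folded in through a CRC32 so the mapping is stable across
    platforms and Python hash randomization.
    """
    return np.random.SeedSequence([int(root_seed), zlib.crc32(label.encode())])


def stage_rng(root_seed: int, label: str) -> np.random.Generator:
    """Generator for a named stage under ``root_seed``."""
    return np.random.default_rng(stage_seed(root_seed, label))
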