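"""Shared helpers: seeded RNG derivation and small numeric utilities."""

from __future__ import annotations

import numpy as np

# stage labels used by the pipeline for per-stage seed derivation
STAGES = (
    "plan",
    "session",
    "rts",
    "packet_loss",
    "preprocess",
    "ride",
    "stats",
)


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage integer seed (< 2**31) from a master seed.

    Deterministic counter scheme: the stage name indexes into a fixed
    list so stages can be re-run in isolation with the same sub-seed.
    """
    if stage in STAGES:
        idx = STAGES.index(stage)
    else:
        # fall back to a stable hash of the label
        idx = sum(ord(c) for c in stage) % 1000 + len(STAGES)
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, idx])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def rng_for(seed: int) -> np.random.Generator:
    return np.random.default_rng(int(seed) & 0x7FFFFFFF)


def ms_to_samples(ms: float, rate: float) -> int:
    """Millisecond -> sample conversion, rounding half away from zero."""
    x = ms * rate / 1000.0
    return int(np.floor(np.abs(x) + 0.5) * np.sign(x))
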