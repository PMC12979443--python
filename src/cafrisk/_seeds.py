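"""Deterministic fan-out of one user seed into named sub-seeds.

Every stochastic stage (cohort generation, train/test split, CV partition,
optimizer dynamics, Shapley permutation sampling) gets its own stream so that
changing one stage's behaviour never perturbs another's draws.
"""

from __future__ import annotations

import hashlib


def derive_seed(seed: int, label: str) -> int:
    """Derive a stable 31-bit sub-seed from (seed, label)."""
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
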