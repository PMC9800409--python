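"""Seeded synthetic network generation for property tests and sweeps.

The generator draws the three defining probabilities of a two-stage binary
network independently and uniformly on [0, 1] — the natural uninformative
choice for exercising the predictor over its whole input domain — and forces
the degenerate and balanced parent priors (0, 0.5, 1) into the head of every
batch so that edge cases are always covered.
"""

from __future__ import annotations

import numpy as np

from .network import TwoStageNetwork

__all__ = ["generate_random_networks", "EDGE_PRIORS"]

EDGE_PRIORS = (0.0, 0.5, 1.0)


def generate_random_networks(count: int, seed: int) -> list[TwoStageNetwork]:
    """Generate ``count`` random networks, reproducibly for a fixed seed.

    The first ``min(count, 3)`` networks carry the forced edge-case priors
    0, 0.5 and 1 (with random conditionals); the remainder are fully random.
    """
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    rng = np.random.default_rng(seed)
    draws = rng.uniform(0.0, 1.0, size=(count, 3))
    for i, prior in enumerate(EDGE_PRIORS[: min(count, 3)]):
        draws[i, 0] = prior
    return [TwoStageNetwork(*row) for row in draws]
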