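"""Quantum-like witness, concurrence estimate, and entanglement entropy.

Social entanglement between the two nodes of a decision network cannot be
measured from a density matrix (the initial conditions of a social system
are unknown), so it is estimated through an observable chain:

1. a *quantum-like witness* angle computed from the two branch projection
   vectors (phase-free by construction, since the branches have disjoint
   support);
2. a fitted periodic map from the witness to a concurrence estimate ``C``;
3. the standard concurrence-to-entropy relation
   ``E = H2((1 + sqrt(1 - C^2)) / 2)`` with ``H2`` the binary Shannon
   entropy in bits;
4. the interference cosine ``cos(theta) = -E`` (destructive only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .network import BranchVectors

__all__ = [
    "EntanglementEstimate",
    "qlw_witness",
    "concurrence_from_witness",
    "entropy_from_concurrence",
    "interference_cos",
    "estimate_entanglement",
]

# Coefficients of the fitted witness -> concurrence map. Taken as printed;
# re-fitting them is out of scope. The harmonic order n = 2**4.
WITNESS_MAP_COEFFS = (0.136, -0.03, 0.02, -0.029, -0.12)
DEFAULT_N = 16


@dataclass(frozen=True)
class EntanglementEstimate:
    """Result of the witness -> concurrence -> entropy chain.

    Attributes
    ----------
    qlw : float
        Witness angle in radians, in [0, pi/2].
    concurrence : float
        Estimated concurrence ``C`` in [0, 1).
    mixing : float
        ``m = (1 + sqrt(1 - C^2)) / 2``, in [0.5, 1].
    entropy : float
        Binary Shannon entropy of ``m`` in bits, in [0, 1].
    clamped : bool
        True when the radicand of the witness map was negative and floored
        at zero (never happens for the fitted coefficients on [0, pi/2],
        but the contract is kept defensive).
    """

    qlw: float
    concurrence: float
    mixing: float
    entropy: float
    clamped: bool

    @property
    def cos_theta(self) -> float:
        return -self.entropy


def qlw_witness(bv: BranchVectors | tuple[np.ndarray, np.ndarray]) -> float:
    """Witness angle between the two branch projection vectors.

    ``qlw = arccos((|v1 - v2|^2 + |v1|^2 - |v2|^2) / (2 |v1 - v2| |v1|))`` —
    the angle opposite ``v2`` in the triangle with sides ``|v1|``, ``|v2|``,
    ``|v1 - v2|``.  For normalized disjoint-support branches this reduces to
    ``arccos(|v1|)`` and lies in [0, pi/2].

    The degenerate ``|v1| = 0`` case returns pi/2, the continuous limit.
    """
    if isinstance(bv, BranchVectors):
        v1, v2 = bv.v1, bv.v2
    else:
        v1, v2 = (np.asarray(v, dtype=complex) for v in bv)
    if not (np.all(np.isfinite(v1.real)) and np.all(np.isfinite(v2.real))):
        raise ValueError("branch vectors must be finite")
    n1 = float(np.linalg.norm(v1))
    n2 = float(np.linalg.norm(v2))
    d = float(np.linalg.norm(v1 - v2))
    if n1 == 0.0:
        return math.pi / 2
    if d == 0.0:
        raise ValueError("qlw witness undefined for v1 == v2")
    cosine = (d * d + n1 * n1 - n2 * n2) / (2.0 * d * n1)
    return math.acos(min(1.0, max(-1.0, cosine)))


def concurrence_from_witness(qlw: float, n: int = DEFAULT_N) -> tuple[float, bool]:
    """Map the witness angle to a concurrence estimate.

    ``C = sqrt(a0 + a1 cos(n q) + a2 sin(n q) + a3 cos(2n q) + a4 sin(2n q))``
    with the fitted coefficients, the radicand floored at zero.  Returns
    ``(C, clamped)`` where ``clamped`` records whether the floor was active.
    Arguments are radians.
    """
    if not math.isfinite(qlw):
        raise ValueError(f"qlw must be finite, got {qlw!r}")
    a0, a1, a2, a3, a4 = WITNESS_MAP_COEFFS
    radicand = (
        a0
        + a1 * math.cos(n * qlw)
        + a2 * math.sin(n * qlw)
        + a3 * math.cos(2 * n * qlw)
        + a4 * math.sin(2 * n * qlw)
    )
    clamped = radicand < 0.0
    return math.sqrt(max(0.0, radicand)), clamped


def entropy_from_concurrence(concurrence: float) -> tuple[float, float]:
    """Mixing parameter and binary entropy of entanglement for a concurrence.

    ``m = (1 + sqrt(1 - C^2)) / 2``;
    ``E = -m log2 m - (1-m) log2(1-m)`` with ``0 log 0 = 0``.
    Strictly increasing in ``C``: ``C=0 -> E=0``, ``C=1 -> E=1``.
    """
    if not 0.0 <= concurrence <= 1.0:
        raise ValueError(f"concurrence must lie in [0, 1], got {concurrence!r}")
    m = (1.0 + math.sqrt(1.0 - concurrence * concurrence)) / 2.0
    if m >= 1.0 or m <= 0.0:
        return m, 0.0
    entropy = -m * math.log2(m) - (1.0 - m) * math.log2(1.0 - m)
    return m, entropy


def interference_cos(entropy: float) -> float:
    """Interference cosine ``cos(theta) = -E``; always in [-1, 0]."""
    if not 0.0 <= entropy <= 1.0:
        raise ValueError(f"entropy must lie in [0, 1], got {entropy!r}")
    return -entropy


def estimate_entanglement(
    bv: BranchVectors, outcome: str = "b1", n: int = DEFAULT_N
) -> EntanglementEstimate:
    """Run the full witness chain with the queried outcome's branch first."""
    if isinstance(bv, BranchVectors):
        v_q, v_o = bv.for_outcome(outcome)
    else:  # pragma: no cover - convenience for raw tuples
        v_q, v_o = bv
    qlw = qlw_witness((v_q, v_o))
    concurrence, clamped = concurrence_from_witness(qlw, n=n)
    mixing, entropy = entropy_from_concurrence(concurrence)
    return EntanglementEstimate(
        qlw=qlw, concurrence=concurrence, mixing=mixing, entropy=entropy, clamped=clamped
    )
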