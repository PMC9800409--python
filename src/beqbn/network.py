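"""Two-stage binary networks and their quantum-like composite state.

A two-stage binary decision task is a Bayesian network with a parent node
``A`` (outcomes ``a1``/``a2``) and a child node ``B`` (outcomes ``b1``/``b2``)
whose distribution is conditioned on ``A``.  Three probabilities specify it
completely: the prior ``Pr(A=a1)`` and the two conditionals
``Pr(B=b1|A=a1)`` and ``Pr(B=b1|A=a2)``.

The quantum-like representation replaces each probability by a complex
amplitude.  The composite state lives in the four-dimensional Hilbert space
spanned by the product basis, fixed here in the ordering
``(a1 b1, a1 b2, a2 b1, a2 b2)``.  Phases are carried structurally but every
observable computed downstream is phase-free; they default to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TwoStageNetwork",
    "NodeAmplitudes",
    "SuperpositionState",
    "BranchVectors",
    "build_superposition",
    "branch_vectors",
    "classical_tpl",
    "validate_probability",
]

#: tolerance for accepting probabilities marginally outside [0, 1]
PROB_TOL = 1e-9

#: valid outcome labels for the child node
OUTCOMES = ("b1", "b2")


def validate_probability(value: float, name: str = "probability") -> float:
    """Validate that ``value`` is a probability; return it nudged into [0, 1].

    Values within ``PROB_TOL`` of the unit interval are accepted and snapped
    to the nearest endpoint; anything further out is an error (never clamped).
    """
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if value < -PROB_TOL or value > 1.0 + PROB_TOL:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return min(1.0, max(0.0, value))


def _check_outcome(outcome: str) -> str:
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}, got {outcome!r}")
    return outcome


@dataclass(frozen=True)
class TwoStageNetwork:
    """The three probabilities defining a two-node binary Bayesian network.

    Parameters
    ----------
    p_a1 : float
        Prior ``Pr(A=a1)``.
    p_b1_given_a1 : float
        Conditional ``Pr(B=b1 | A=a1)``.
    p_b1_given_a2 : float
        Conditional ``Pr(B=b1 | A=a2)``.
    labels : tuple of (str, str) pairs, optional
        Outcome names for nodes A and B, e.g.
        ``(("defect", "cooperate"), ("defect", "cooperate"))``.

    The complementary quantities ``Pr(A=a2)`` and ``Pr(B=b2|A=·)`` are derived
    on demand and never stored.
    """

    p_a1: float
    p_b1_given_a1: float
    p_b1_given_a2: float
    labels: tuple[tuple[str, str], tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "p_a1", validate_probability(self.p_a1, "p_a1"))
        object.__setattr__(
            self, "p_b1_given_a1", validate_probability(self.p_b1_given_a1, "p_b1_given_a1")
        )
        object.__setattr__(
            self, "p_b1_given_a2", validate_probability(self.p_b1_given_a2, "p_b1_given_a2")
        )

    @property
    def p_a2(self) -> float:
        return 1.0 - self.p_a1

    def p_b_given_a(self, outcome: str, parent: str) -> float:
        """Conditional ``Pr(B=outcome | A=parent)`` for any outcome pair."""
        _check_outcome(outcome)
        if parent not in ("a1", "a2"):
            raise ValueError(f"parent must be 'a1' or 'a2', got {parent!r}")
        p = self.p_b1_given_a1 if parent == "a1" else self.p_b1_given_a2
        return p if outcome == "b1" else 1.0 - p

    def joint(self, parent: str, outcome: str) -> float:
        """Joint ``Pr(A=parent, B=outcome)`` by the product rule."""
        pa = self.p_a1 if parent == "a1" else self.p_a2
        return pa * self.p_b_given_a(outcome, parent)


@dataclass(frozen=True)
class NodeAmplitudes:
    """Per-node wave-function amplitudes kappa_i = sqrt(probability).

    The six phases ``gamma`` attached to the node wave functions are formally
    unknown; they default to zero and are never consumed by any observable.
    (The composite-state phases theta_i are implied sums of gammas; the
    mapping is documentation only since everything downstream is phase-free.)
    """

    kappa1: float  # sqrt Pr(A=a1)
    kappa2: float  # sqrt Pr(B=b1 | A=a1)
    kappa3: float  # sqrt Pr(B=b1 | A=a2)
    gammas: tuple[float, ...] = (0.0,) * 6

    @classmethod
    def from_network(cls, net: TwoStageNetwork) -> "NodeAmplitudes":
        return cls(
            kappa1=math.sqrt(net.p_a1),
            kappa2=math.sqrt(net.p_b1_given_a1),
            kappa3=math.sqrt(net.p_b1_given_a2),
        )


@dataclass(frozen=True)
class SuperpositionState:
    """Four non-negative joint amplitudes over the basis (a1b1, a1b2, a2b1, a2b2).

    ``amplitudes`` squares to the joint distribution of the classical network;
    ``phases`` are formally unknown and default to zero.
    """

    amplitudes: tuple[float, float, float, float]
    phases: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        norm = sum(c * c for c in self.amplitudes)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"amplitudes must be normalized, |c|^2 = {norm!r}")

    @property
    def vector(self) -> np.ndarray:
        """Complex state vector c_i * exp(i theta_i)."""
        c = np.asarray(self.amplitudes, dtype=float)
        th = np.asarray(self.phases, dtype=float)
        return c * np.exp(1j * th)

    def joint_probabilities(self) -> np.ndarray:
        return np.square(np.asarray(self.amplitudes, dtype=float))


@dataclass(frozen=True)
class BranchVectors:
    """Projections of the composite state onto the two child outcomes.

    ``v1`` keeps the ``b1`` components (entries 1 and 3 of the basis), ``v2``
    the ``b2`` components (entries 2 and 4); their supports are disjoint so
    they are exactly orthogonal and their squared norms partition |psi|^2.
    """

    v1: np.ndarray
    v2: np.ndarray

    def for_outcome(self, outcome: str) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(v_outcome, v_other)``."""
        _check_outcome(outcome)
        return (self.v1, self.v2) if outcome == "b1" else (self.v2, self.v1)


# projectors I (x) P_{B=b} in the fixed basis ordering
PROJECTOR_B1 = np.diag([1.0, 0.0, 1.0, 0.0])
PROJECTOR_B2 = np.diag([0.0, 1.0, 0.0, 1.0])


def build_superposition(
    net: TwoStageNetwork, phases: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
) -> SuperpositionState:
    """Form the composite superposition state from a network.

    The amplitudes are products of the per-node square-root amplitudes:
    ``c1 = k1 k2``, ``c2 = k1 sqrt(1-k2^2)``, ``c3 = sqrt(1-k1^2) k3``,
    ``c4 = sqrt(1-k1^2) sqrt(1-k3^2)``, so that ``c_i^2`` reproduces the
    joint distribution of the classical network.
    """
    k = NodeAmplitudes.from_network(net)
    k1c = math.sqrt(max(0.0, 1.0 - k.kappa1**2))
    c = (
        k.kappa1 * k.kappa2,
        k.kappa1 * math.sqrt(max(0.0, 1.0 - k.kappa2**2)),
        k1c * k.kappa3,
        k1c * math.sqrt(max(0.0, 1.0 - k.kappa3**2)),
    )
    return SuperpositionState(amplitudes=c, phases=tuple(float(p) for p in phases))


def branch_vectors(state: SuperpositionState) -> BranchVectors:
    """Apply ``I (x) P_{B=b1}`` and ``I (x) P_{B=b2}`` to the state vector."""
    psi = state.vector
    return BranchVectors(v1=PROJECTOR_B1 @ psi, v2=PROJECTOR_B2 @ psi)


def classical_tpl(net: TwoStageNetwork, outcome: str = "b1") -> float:
    """Classical total-probability-law marginal ``Pr(B=outcome)``.

    ``Pr(b) = sum_a Pr(b|a) Pr(a)`` — the baseline that human data violate
    under uncertainty; no interference term.
    """
    _check_outcome(outcome)
    return net.joint("a1", outcome) + net.joint("a2", outcome)
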