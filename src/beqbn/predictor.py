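"""The biased entangled quantum-like predictor and its classical baseline.

Predicted probability of a child outcome under uncertainty about the parent:

    Pr(B=b) = normalize( classical_part + magnitude * cos(theta) + U(prior) )

where ``classical_part`` is the Born-rule diagonal (equal to the classical
total-probability marginal), ``cos(theta) = -E_Sh`` comes from the witness
chain, ``magnitude`` is the interference cross-term amplitude, and ``U`` is a
Gaussian-shaped bias potential of the parent prior peaking at 0.25/0.75.

Two of the model's ingredients admit more than one internally consistent
reading, so they are configuration modes rather than hard-coded choices:

* ``interference_magnitude`` — ``born_cross_term`` uses the Born-rule cross
  term ``2 c_q c_o`` of the two path amplitudes into the queried outcome;
  ``literal_product`` uses the bare product ``c_q c_o`` (the path-amplitude
  reading of the projector expansion, which omits the factor 2).
* ``normalization`` — ``clamp`` truncates the raw sum into [0, 1];
  ``sum_normalize`` divides by the sum of the raw values over both outcomes.
* ``entanglement_scope`` — ``queried_outcome`` computes one witness chain
  (for the queried outcome) and reuses its entropy wherever needed;
  ``per_outcome`` recomputes the chain from each outcome's own branch.

The defaults are the modes selected by the calibration grid in
:mod:`beqbn.evaluation`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

from .entanglement import DEFAULT_N, EntanglementEstimate, estimate_entanglement
from .network import (
    BranchVectors,
    TwoStageNetwork,
    branch_vectors,
    build_superposition,
    classical_tpl,
    validate_probability,
)

__all__ = [
    "PredictorConfig",
    "PredictionBreakdown",
    "bias_potential",
    "beqbn_predict",
    "cbn_predict",
    "MAGNITUDE_MODES",
    "NORMALIZATION_MODES",
    "SCOPE_MODES",
]

MAGNITUDE_MODES = ("born_cross_term", "literal_product")
NORMALIZATION_MODES = ("clamp", "sum_normalize")
SCOPE_MODES = ("queried_outcome", "per_outcome")

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class PredictorConfig:
    """Discrete modes resolving the model's ambiguous ingredients."""

    interference_magnitude: str = "born_cross_term"
    normalization: str = "clamp"
    entanglement_scope: str = "queried_outcome"
    n_witness: int = DEFAULT_N

    def __post_init__(self) -> None:
        if self.interference_magnitude not in MAGNITUDE_MODES:
            raise ValueError(
                f"interference_magnitude must be one of {MAGNITUDE_MODES}, "
                f"got {self.interference_magnitude!r}"
            )
        if self.normalization not in NORMALIZATION_MODES:
            raise ValueError(
                f"normalization must be one of {NORMALIZATION_MODES}, "
                f"got {self.normalization!r}"
            )
        if self.entanglement_scope not in SCOPE_MODES:
            raise ValueError(
                f"entanglement_scope must be one of {SCOPE_MODES}, "
                f"got {self.entanglement_scope!r}"
            )
        if int(self.n_witness) < 1:
            raise ValueError(f"n_witness must be a positive integer, got {self.n_witness!r}")
        object.__setattr__(self, "n_witness", int(self.n_witness))

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PredictionBreakdown:
    """Final probability together with the additive components producing it.

    ``raw = classical_part + interference_term + bias_term`` exactly;
    ``probability`` is ``raw`` after the configured normalization.
    """

    classical_part: float
    interference_term: float
    bias_term: float
    raw: float
    probability: float
    entanglement: EntanglementEstimate
    config: PredictorConfig
    outcome: str

    def as_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "classical_part": self.classical_part,
            "interference_term": self.interference_term,
            "bias_term": self.bias_term,
            "raw": self.raw,
            "probability": self.probability,
            "qlw": self.entanglement.qlw,
            "concurrence": self.entanglement.concurrence,
            "mixing": self.entanglement.mixing,
            "entropy": self.entanglement.entropy,
            "concurrence_clamped": self.entanglement.clamped,
            "config": self.config.as_dict(),
        }


def bias_potential(p_a1: float) -> float:
    """Bias potential ``U`` of the parent prior.

    A Gaussian bump of width 0.1 centred on 0.75 (prior >= 0.5) or 0.25
    (prior < 0.5), scaled by 1/sqrt(2 pi):

        U(p) = exp(-100 (p - 0.75)^2) / sqrt(2 pi)   for p >= 0.5
        U(p) = exp(-100 (p - 0.25)^2) / sqrt(2 pi)   for p <  0.5

    Models the mind's tilt toward the likelier parent outcome: maximal
    (1/sqrt(2 pi) ~ 0.399) at 0.75/0.25, near zero at 0, 0.5 and 1, symmetric
    under p -> 1 - p, continuous at 0.5.
    """
    p = validate_probability(p_a1, "p_a1")
    centre = 0.75 if p >= 0.5 else 0.25
    return math.exp(-100.0 * (p - centre) ** 2) / _SQRT_2PI


def _branch_amplitudes(state_amplitudes: tuple, outcome: str) -> tuple[float, float]:
    """Two path amplitudes reaching ``outcome``: (via a1, via a2)."""
    c1, c2, c3, c4 = state_amplitudes
    return (c1, c3) if outcome == "b1" else (c2, c4)


def _other(outcome: str) -> str:
    return "b2" if outcome == "b1" else "b1"


def _raw_value(
    state_amplitudes: tuple,
    outcome: str,
    entanglement: EntanglementEstimate,
    bias: float,
    cfg: PredictorConfig,
) -> tuple[float, float, float]:
    """Return (classical_part, interference_term, raw) for one outcome."""
    via_a1, via_a2 = _branch_amplitudes(state_amplitudes, outcome)
    classical_part = via_a1 * via_a1 + via_a2 * via_a2
    magnitude = via_a1 * via_a2
    if cfg.interference_magnitude == "born_cross_term":
        magnitude *= 2.0
    interference = magnitude * entanglement.cos_theta
    return classical_part, interference, classical_part + interference + bias


def beqbn_predict(
    net: TwoStageNetwork,
    outcome: str = "b1",
    config: PredictorConfig | None = None,
) -> PredictionBreakdown:
    """Predict ``Pr(B=outcome)`` under uncertainty about the parent node.

    Executes the full chain: superposition state, branch projections, witness
    angle, concurrence, entanglement entropy, interference cosine, bias
    potential, and the configured combination/normalization.  The result is
    always in [0, 1]; phases never enter any quantity.
    """
    cfg = config or PredictorConfig()
    state = build_superposition(net)
    bv = branch_vectors(state)
    bias = bias_potential(net.p_a1)

    def chain_for(b: str) -> EntanglementEstimate:
        if cfg.entanglement_scope == "per_outcome":
            return estimate_entanglement(bv, outcome=b, n=cfg.n_witness)
        return estimate_entanglement(bv, outcome=outcome, n=cfg.n_witness)

    ent_q = chain_for(outcome)
    classical_part, interference, raw = _raw_value(
        state.amplitudes, outcome, ent_q, bias, cfg
    )

    if cfg.normalization == "clamp":
        probability = min(1.0, max(0.0, raw))
    else:
        other = _other(outcome)
        _, _, raw_other = _raw_value(state.amplitudes, other, chain_for(other), bias, cfg)
        total = raw + raw_other
        probability = raw / total if total > 0.0 else 0.5

    return PredictionBreakdown(
        classical_part=classical_part,
        interference_term=interference,
        bias_term=bias,
        raw=raw,
        probability=probability,
        entanglement=ent_q,
        config=cfg,
        outcome=outcome,
    )


def cbn_predict(net: TwoStageNetwork, outcome: str = "b1") -> float:
    """Classical Bayesian-network prediction (total probability law)."""
    return classical_tpl(net, outcome)
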