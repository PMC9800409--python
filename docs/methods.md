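# Methods

## Problem and model

The package predicts the marginal probability of a child outcome in a
two-stage binary decision task when the parent event is unresolved — the
regime where observed human frequencies violate classical total-probability
marginalization (the disjunction effect / sure-thing-principle violations).
The model treats the decision-maker as part of a composite "social" system
represented quantum-like: the two nodes of the Bayesian network become a
two-qubit state in the four-dimensional product Hilbert space with basis
fixed as `(a1b1, a1b2, a2b1, a2b2)`.

Amplitudes are square roots of the classical joint probabilities, so squared
amplitudes reproduce the classical network exactly; phases are carried
structurally but are formally unknown. The model is deliberately phase-free:
every observable it computes is invariant under any assignment of the four
phases (property-tested to 1e-12), because the branch projections used by
the witness have disjoint support. The per-node wave functions carry six
phases while the composite state has four; the implied mapping (sums of
node phases) is documentation only and is never consumed.

The prediction for outcome `b1` is

    normalize( c1² + c3² + magnitude · cosθ + U(p_a1) )

with `cosθ = −E_Sh` from the entanglement chain below, and `U` the bias
potential. Interference is destructive only; the entropy bound `E_Sh ≤ 1`
together with `2 c1 c3 ≤ c1² + c3²` guarantees the raw value is never
negative before normalization.

## The entanglement chain

**Witness.** `qlw(v1, v2) = arccos[(|v1−v2|² + |v1|² − |v2|²)/(2|v1−v2||v1|)]`
is the angle opposite `v2` in the triangle with sides `|v1|`, `|v2|`,
`|v1−v2|`. Because `v1 ⟂ v2` exactly (disjoint support) and the state is
normalized, this reduces to `arccos |v1|` and lies in `[0, π/2]`. The
implementation evaluates the general formula; a test cross-checks the closed
form over random networks. Degenerate case `|v1| = 0`: the function returns
`π/2`, the continuous limit of `arccos |v1|`, avoiding a 0/0.

**Concurrence.** A fitted two-harmonic map
`C = √(0.136 − 0.03 cos(nq) + 0.02 sin(nq) − 0.029 cos(2nq) − 0.12 sin(2nq))`
with `n = 2⁴ = 16`. The coefficients are taken as published and not
re-fitted (re-fitting is explicitly out of scope); `n` is exposed as a knob
for sensitivity analysis only. Arguments are radians — `qlw` is produced by
an inverse cosine, so a degree reading would be inconsistent. The radicand's
harmonics are phase-locked such that its global minimum is ≈ 1.79e-4 > 0
(verified on a 2·10⁶-point grid over a full period), so `C ∈ (0, √0.335]`
always; a defensive floor at zero with a `clamped` flag is nevertheless kept
in the contract, and tests assert it never activates.

**Entropy.** `m = (1 + √(1−C²))/2`, `E_Sh = −m log₂ m − (1−m) log₂(1−m)`
with `0·log 0 = 0`; strictly increasing in `C`, with exact endpoints
`C=0 → E=0`, `C=1 → E=1`. Written as the two-line closed form rather than
through a generic entropy routine to keep the `0·log 0` endpoint exact.

**Bias potential.** A Gaussian bump of 1/e half-width 0.1, centre 0.75 for
`p ≥ 0.5` and 0.25 otherwise, scaled by `1/√(2π)` so the maximum is
≈ 0.3989. It is continuous at 0.5 (both branches give `exp(−6.25)/√(2π)` ≈
7.7e-4), symmetric under `p → 1−p`, and negligible at 0, 0.5 and 1 — no tilt
without inequality, no interference without uncertainty. `p = 0.5` exactly
takes the `≥ 0.5` branch; the branches agree there, which a test verifies.

## Configuration modes and calibration

The published formulation leaves three ingredients ambiguous, so each is an
explicit mode of `PredictorConfig`:

- **interference_magnitude** — the projector expansion's cross term is
  `2 c1 c3 cosθ` under the Born rule (`born_cross_term`, default), while the
  printed closed form reads as the bare product of the four path amplitudes,
  `c1 c3` (`literal_product`).
- **normalization** — the final expression caps at 1 (`clamp`, default,
  with a floor at 0 to complete the probability contract), while the
  earlier normalization-factor presentation suggests dividing by the sum
  over both outcomes (`sum_normalize`; under it the two outcomes sum to 1
  exactly, under clamp they need not — documented behavior).
- **entanglement_scope** — one witness chain computed for the queried
  outcome and reused (`queried_outcome`, default, the literal pseudo-code),
  or a chain per outcome (`per_outcome`).

`calibrate()` enumerates the full 2×2×2 grid deterministically and scores
each candidate by the mean squared deviation of its six signed error cells
(four prisoner's-dilemma rows + two face-task rows, equally weighted — both
published headline RMSEs derive from exactly these cells) from the published
error columns of the biased model. Ties break by enumeration order, defaults
first. The selected configuration is Born cross term + clamp +
queried-outcome.

Under it the package obtains a prisoner's-dilemma RMSE of 3.09 percentage
points (published: 3.40; within the 0.5-pp match band) and a face-task RMSE
of 3.43 (published: 5.07; **no** candidate comes within 0.5 pp). Inverting
the published error cells shows the entropy values they imply are not
consistent with the published concurrence-map coefficients under any mode in
the grid, so the face-task column cannot be reproduced exactly from the
published formulas; the calibration result therefore carries a `discrepancy`
flag and the per-candidate grid report is the authoritative record. The
reproduction errs on the favorable side — the recomputed face-task RMSE is
lower than the published one — and the calibrated model beats the classical
baseline on both benchmarks, preserving the published ranking.

## Benchmarks and synthetic data

The two benchmarks are hard-coded fixtures matching the published tables
digit-for-digit: four prisoner's-dilemma variants (parent prior 0.5,
conditionals and observed defection rates per experiment; the "Li and
Taplini" spelling is preserved from the source table) and the
face-categorization task (priors 0.84/0.17 for wide/narrow faces, attack
conditionals, and the decide-alone attack rates). Errors are
`(predicted − empirical) × 100` in percentage points — the sign convention
recovered by recomputing the classical column — with RMSE over rows.
Rounding to two decimals happens only at presentation.

`generate_random_networks(count, seed)` draws the three defining
probabilities i.i.d. uniform on [0, 1] — the uninformative choice for
exercising the predictor over its entire admissible domain — and forces
parent priors 0, 0.5 and 1 into the head of every batch so the degenerate
and balanced regimes are always covered. It emulates nothing about real
behavioral data (no response noise, no sampling error, no correlation
between conditionals); passing property sweeps on it demonstrates contract
properties (range, phase freedom, limits), not predictive validity on human
data, which only the two empirical benchmarks address.

## Numerical choices

- Probabilities are validated to [0, 1] with tolerance 1e-9; values inside
  the tolerance band are snapped to the endpoint, anything further is an
  error, never clamped.
- State normalization is asserted to 1e-9 at construction (amplitudes are
  built from exact square roots, so the slack only covers rounding).
- The witness's cosine argument is clipped to [−1, 1] before `arccos` to
  absorb floating-point excursions at the boundaries.
- All internal arithmetic is double precision end to end; CSV output uses
  '.' decimals, UTF-8, ASCII minus signs.

## Problem sizes

Everything here is desk-scale: the benchmarks have 4 + 2 rows, the
calibration grid 8 candidates, and the property sweeps use 1000 random
networks and 1000 random phase draws, which keeps the full test suite and
the acceptance script each well under a minute on one CPU.

## Limitations

- Only two-node, two-state-per-node networks; larger structures are out of
  scope.
- The concurrence map's coefficients are used as published; no re-fitting,
  so the model inherits whatever rounding those printed coefficients carry —
  the likely cause of the face-task discrepancy above.
- The witness chain estimates entanglement from a single observable; it is
  not the true two-qubit concurrence of a density matrix, which the model by
  design never materializes.
- The six competing quantum-like predictors appear only as published
  reference error columns, not as implementations.
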