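# beqbn — biased entangled quantum-like Bayesian networks

Human choices in two-stage binary tasks systematically violate the classical
total probability law (TPL). In prisoner's-dilemma experiments, players who
are told the other prisoner's choice defect with probability 0.97 (after
"defect") or 0.84 (after "cooperate"), yet defect only with probability 0.63
when the other's choice is unknown — far below any classical mixture of the
two conditionals. `beqbn` implements a quantum-like predictor for such tasks:
a Bayesian network over a parent node `A` and child node `B` whose
probabilities are replaced by complex amplitudes, so that marginalizing over
the unobserved parent produces an interference term absent from the
classical calculus.

## Model

A task is specified by three probabilities: the prior `Pr(A=a1)` and the
conditionals `Pr(B=b1|A=a1)`, `Pr(B=b1|A=a2)`. The composite state over the
basis `(a1b1, a1b2, a2b1, a2b2)` has amplitudes `c_i` equal to the square
roots of the classical joint probabilities, carrying formally unknown
phases. The predicted child marginal is

    Pr(B=b1) = min{1, c1² + c3² + 2 c1 c3 cos θ + U(Pr(A=a1))}

where the interference cosine is estimated through a phase-free chain:

1. **Witness angle.** Project the state onto the two child outcomes
   (`v1` keeps the `b1` components, `v2` the `b2` components) and compute
   `qlw = arccos[(|v1−v2|² + |v1|² − |v2|²) / (2 |v1−v2| |v1|)]`, which for a
   normalized state equals `arccos √(c1²+c3²)` and is independent of all
   phases.
2. **Concurrence.** `C = √(0.136 − 0.03 cos(n·qlw) + 0.02 sin(n·qlw) −
   0.029 cos(2n·qlw) − 0.12 sin(2n·qlw))` with harmonic order `n = 16`, a
   fitted periodic map from the witness to the standard two-qubit
   entanglement measure.
3. **Entanglement entropy.** `m = (1 + √(1−C²))/2` and
   `E = −m log₂ m − (1−m) log₂(1−m)`; then `cos θ = −E` (interference is
   destructive only).
4. **Bias potential.** `U(p) = exp(−100 (p − 0.75)²)/√(2π)` for `p ≥ 0.5`
   (centre 0.25 otherwise): the mind's tilt toward the likelier parent
   outcome, maximal at priors 0.25/0.75 and negligible at 0, 0.5 and 1.

The classical TPL baseline `Pr(b1) = Σ_a Pr(b1|a) Pr(a)` ships alongside.
Ambiguous ingredients of the published formulation (interference-term
magnitude, output normalization, entanglement scope) are explicit
configuration modes; a deterministic calibration grid selects the
combination that best reproduces the published benchmark error tables. See
`docs/methods.md` for details and known limitations.

## Worked example

Write a network spec for the averaged prisoner's-dilemma task and predict
the probability that the second player defects without knowing the first
player's choice:

```bash
$ cat shafir.yaml
prior_a1: 0.5
p_b1_given_a1: 0.97
p_b1_given_a2: 0.84

$ beqbn predict --network shafir.yaml
{
  "outcome": "b1",
  "classical_part": 0.905,
  "interference_term": -0.2689192342455188,
  "bias_term": 0.0007701397753170604,
  "raw": 0.6368509055297983,
  "probability": 0.6368509055297983,
  "qlw": 0.31332210582037023,
  "concurrence": 0.44702173158575387,
  "mixing": 0.947261548618388,
  "entropy": 0.2979177338220576,
  "concurrence_clamped": false,
  "config": { ... },
  "classical_tpl": 0.905
}
```

The classical marginal is 0.905; the destructive interference term −0.269
(the Born cross term 2·c1·c3 = 0.903 times −E_Sh = −0.298) pulls the
prediction down to 0.637, against the observed 0.63 — the TPL violation the
model exists to capture. The bias term is negligible here because the
parent prior is exactly 0.5.

The same chain is available as a scikit-learn estimator:

```python
import numpy as np
from beqbn import QuantumLikePredictor, load_benchmark, networks_to_array

bench = load_benchmark("pd")
X = networks_to_array([r.network for r in bench.rows])
y = np.array([r.empirical for r in bench.rows])
model = QuantumLikePredictor().fit(X, y)   # calibrates the mode grid
model.predict(X)                            # array([0.6369, 0.6668, 0.6299, 0.8732])
```

Other subcommands: `beqbn reproduce --benchmark pd --out DIR` (CSV error
table plus provenance JSON), `beqbn calibrate --out report.json` (the full
configuration grid report), and `beqbn simulate --count N --seed S` (seeded
random networks with predictions, for property sweeps).

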