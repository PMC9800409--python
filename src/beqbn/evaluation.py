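"""Benchmarks, error tables, and calibration of the predictor configuration.

Two published two-stage binary benchmarks ship as fixtures:

* ``pd`` — four prisoner's-dilemma experiments (equal parent prior 0.5);
  the queried quantity is the probability that the second player defects
  when the first player's choice is unknown.
* ``faces`` — a categorize-then-decide task on face stimuli (unequal parent
  priors 0.84 / 0.17); the queried quantity is the probability of attacking
  in the decide-alone condition.

Errors are reported in percentage points, ``(predicted - empirical) * 100``,
with RMSE over the rows of a benchmark.  Published error columns for the
classical baseline, six competing quantum-like predictors, and the biased
entangled model are retained as reference constants; ``calibrate`` picks the
configuration mode combination whose error cells best match the reference
biased-model columns and flags any benchmark where no combination comes
within a half percentage point of the reference RMSE.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import pandas as pd

from .network import TwoStageNetwork
from .predictor import (
    MAGNITUDE_MODES,
    NORMALIZATION_MODES,
    SCOPE_MODES,
    PredictorConfig,
    beqbn_predict,
    cbn_predict,
)

__all__ = [
    "BenchmarkRow",
    "BenchmarkDataset",
    "ErrorTable",
    "CalibrationCandidate",
    "CalibrationResult",
    "load_benchmark",
    "evaluate",
    "evaluate_cbn",
    "evaluate_beqbn",
    "calibrate",
    "REFERENCE_ERRORS",
    "REFERENCE_RMSE",
]


@dataclass(frozen=True)
class BenchmarkRow:
    label: str
    network: TwoStageNetwork
    empirical: float


@dataclass(frozen=True)
class BenchmarkDataset:
    name: str
    rows: tuple[BenchmarkRow, ...]
    source: str


# "Li and Taplini" spelling preserved from the source table (sic).
_PD_ROWS = (
    ("Shafir and Tversky", 0.5, 0.97, 0.84, 0.63),
    ("Li and Taplini", 0.5, 0.82, 0.77, 0.72),
    ("Busemeyer et al.", 0.5, 0.91, 0.84, 0.66),
    ("Hristova and Grinberg", 0.5, 0.97, 0.93, 0.88),
)

_FACES_ROWS = (
    ("Wide face", 0.84, 0.35, 0.52, 0.39),
    ("Narrow face", 0.17, 0.41, 0.63, 0.69),
)

_BENCHMARKS = {
    "pd": BenchmarkDataset(
        name="pd",
        rows=tuple(
            BenchmarkRow(label, TwoStageNetwork(p, q1, q2), emp)
            for label, p, q1, q2, emp in _PD_ROWS
        ),
        source="average defection rates across published prisoner's dilemma variants",
    ),
    "faces": BenchmarkDataset(
        name="faces",
        rows=tuple(
            BenchmarkRow(label, TwoStageNetwork(p, q1, q2), emp)
            for label, p, q1, q2, emp in _FACES_ROWS
        ),
        source="face categorization-then-decision experiment, decide-alone condition",
    ),
}

# Published signed error columns (percentage points) per predictor; the six
# competing quantum-like models are reference constants only and are not
# implemented here.
REFERENCE_ERRORS: dict[str, dict[str, tuple[float, ...]]] = {
    "pd": {
        "cbn": (27.50, 7.50, 21.50, 7.00),
        "qdt": (2.50, -17.50, -3.50, -18.00),
        "qbn_heuristic": (1.08, -0.78, 13.95, 2.64),
        "qbn_deng_entropy": (-11.16, -14.07, -5.31, 2.45),
        "qbn_wave_coefficient": (17.01, -6.96, 8.25, -0.51),
        "bqbn": (20.57, -12.84, 9.5, 2.42),
        "peqbn": (0.54, -6.98, 5.58, 1.14),
        "beqbn": (-4.54, -2.98, 3.40, -2.33),
    },
    "faces": {
        "cbn": (-1.28, -9.74),
        "qdt": (-26.28, -34.74),
        "qbn_heuristic": (-15.80, 9.89),
        "qbn_deng_entropy": (4.24, -16.85),
        "qbn_wave_coefficient": (-14.96, 7.96),
        "bqbn": (29.72, -33.90),
        "peqbn": (-6.01, -20.69),
        "beqbn": (7.05, -1.30),
    },
}

# Published headline RMSEs (percentage points) for the biased model.
REFERENCE_RMSE = {"pd": 3.40, "faces": 5.07}


def load_benchmark(name: str) -> BenchmarkDataset:
    """Return a packaged benchmark, ``pd`` or ``faces``."""
    try:
        return _BENCHMARKS[name]
    except KeyError:
        raise ValueError(
            f"unknown benchmark {name!r}; available: {sorted(_BENCHMARKS)}"
        ) from None


def _rmse(errors) -> float:
    return math.sqrt(sum(e * e for e in errors) / len(errors))


@dataclass(frozen=True)
class ErrorTable:
    """Signed per-row errors (percentage points) and their RMSE."""

    benchmark: str
    labels: tuple[str, ...]
    empirical: tuple[float, ...]
    predicted: tuple[float, ...]
    per_row_errors: tuple[float, ...]
    rmse: float
    predictor_id: str
    config: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: one row per dataset plus the shared RMSE column."""
        return pd.DataFrame(
            {
                "dataset": self.labels,
                "predictor": self.predictor_id,
                "empirical": self.empirical,
                "predicted": [round(p, 6) for p in self.predicted],
                "error": [round(e, 2) for e in self.per_row_errors],
                "rmse": round(self.rmse, 2),
            }
        )


def evaluate(
    predict_fn,
    dataset: BenchmarkDataset,
    predictor_id: str = "custom",
    config: dict | None = None,
) -> ErrorTable:
    """Score a predictor (callable ``network -> probability``) on a benchmark.

    Errors are ``(predicted - empirical) * 100``; RMSE is over the rows.
    Internal arithmetic stays at full precision; rounding is presentation only.
    """
    if not dataset.rows:
        raise ValueError("dataset has no rows")
    predicted = tuple(float(predict_fn(row.network)) for row in dataset.rows)
    errors = tuple(
        (p - row.empirical) * 100.0 for p, row in zip(predicted, dataset.rows)
    )
    return ErrorTable(
        benchmark=dataset.name,
        labels=tuple(r.label for r in dataset.rows),
        empirical=tuple(r.empirical for r in dataset.rows),
        predicted=predicted,
        per_row_errors=errors,
        rmse=_rmse(errors),
        predictor_id=predictor_id,
        config=config,
    )


def evaluate_cbn(dataset: BenchmarkDataset) -> ErrorTable:
    """Classical total-probability baseline on a benchmark."""
    return evaluate(lambda net: cbn_predict(net, "b1"), dataset, predictor_id="cbn")


def evaluate_beqbn(
    dataset: BenchmarkDataset, config: PredictorConfig | None = None
) -> ErrorTable:
    """Biased entangled quantum-like predictor on a benchmark."""
    cfg = config or PredictorConfig()
    return evaluate(
        lambda net: beqbn_predict(net, "b1", cfg).probability,
        dataset,
        predictor_id="beqbn",
        config=cfg.as_dict(),
    )


@dataclass(frozen=True)
class CalibrationCandidate:
    config: PredictorConfig
    pd_errors: tuple[float, ...]
    pd_rmse: float
    faces_errors: tuple[float, ...]
    faces_rmse: float
    deviation: float  # mean squared deviation from the reference error cells

    def as_dict(self) -> dict:
        return {
            "config": self.config.as_dict(),
            "pd_errors": [round(e, 4) for e in self.pd_errors],
            "pd_rmse": round(self.pd_rmse, 4),
            "faces_errors": [round(e, 4) for e in self.faces_errors],
            "faces_rmse": round(self.faces_rmse, 4),
            "deviation": round(self.deviation, 4),
        }


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the exhaustive mode-grid calibration.

    ``best_config`` minimizes the mean squared deviation over all six
    reference error cells (four PD + two faces, equally weighted); ties are
    broken by enumeration order (defaults first).  ``*_matched`` report
    whether *any* candidate lands within ``rmse_tolerance`` percentage points
    of the reference RMSE for that benchmark; ``discrepancy`` is set when at
    least one benchmark has no matching candidate, in which case this report
    (best-achievable RMSE per candidate) is the authoritative record.
    """

    best_config: PredictorConfig
    candidates: tuple[CalibrationCandidate, ...]
    pd_matched: bool
    faces_matched: bool
    rmse_tolerance: float

    @property
    def discrepancy(self) -> bool:
        return not (self.pd_matched and self.faces_matched)

    @property
    def best(self) -> CalibrationCandidate:
        for cand in self.candidates:
            if cand.config == self.best_config:
                return cand
        raise RuntimeError("best_config missing from candidates")  # pragma: no cover

    def as_dict(self) -> dict:
        return {
            "best_config": self.best_config.as_dict(),
            "pd_rmse": round(self.best.pd_rmse, 4),
            "faces_rmse": round(self.best.faces_rmse, 4),
            "reference_rmse": dict(REFERENCE_RMSE),
            "rmse_tolerance": self.rmse_tolerance,
            "pd_matched": self.pd_matched,
            "faces_matched": self.faces_matched,
            "discrepancy": self.discrepancy,
            "candidates": [c.as_dict() for c in self.candidates],
        }


def calibrate(
    dataset_pd: BenchmarkDataset | None = None,
    dataset_faces: BenchmarkDataset | None = None,
    rmse_tolerance: float = 0.5,
    n_witness: int = 16,
) -> CalibrationResult:
    """Exhaustively score every mode combination against the reference columns.

    Deterministic and idempotent: the 2 x 2 x 2 grid is enumerated in a fixed
    order and scored by the mean squared deviation of its six error cells from
    the reference biased-model columns.
    """
    dataset_pd = dataset_pd or load_benchmark("pd")
    dataset_faces = dataset_faces or load_benchmark("faces")
    ref_pd = REFERENCE_ERRORS["pd"]["beqbn"]
    ref_faces = REFERENCE_ERRORS["faces"]["beqbn"]

    candidates = []
    for mag, norm, scope in itertools.product(
        MAGNITUDE_MODES, NORMALIZATION_MODES, SCOPE_MODES
    ):
        cfg = PredictorConfig(mag, norm, scope, n_witness)
        tab_pd = evaluate_beqbn(dataset_pd, cfg)
        tab_faces = evaluate_beqbn(dataset_faces, cfg)
        cells = list(tab_pd.per_row_errors) + list(tab_faces.per_row_errors)
        refs = list(ref_pd) + list(ref_faces)
        deviation = sum((c - r) ** 2 for c, r in zip(cells, refs)) / len(cells)
        candidates.append(
            CalibrationCandidate(
                config=cfg,
                pd_errors=tab_pd.per_row_errors,
                pd_rmse=tab_pd.rmse,
                faces_errors=tab_faces.per_row_errors,
                faces_rmse=tab_faces.rmse,
                deviation=deviation,
            )
        )

    best = min(range(len(candidates)), key=lambda i: candidates[i].deviation)
    pd_matched = any(
        abs(c.pd_rmse - REFERENCE_RMSE["pd"]) <= rmse_tolerance for c in candidates
    )
    faces_matched = any(
        abs(c.faces_rmse - REFERENCE_RMSE["faces"]) <= rmse_tolerance for c in candidates
    )
    return CalibrationResult(
        best_config=candidates[best].config,
        candidates=tuple(candidates),
        pd_matched=pd_matched,
        faces_matched=faces_matched,
        rmse_tolerance=rmse_tolerance,
    )
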