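"""Scikit-learn style estimators wrapping the two predictors.

Rows of ``X`` are two-stage binary networks given as the three defining
probabilities ``(p_a1, p_b1_given_a1, p_b1_given_a2)``; ``predict`` returns
the probability of the queried child outcome for each row.

``QuantumLikePredictor.fit`` performs the discrete calibration: it enumerates
every combination of the model's ambiguity modes and keeps the one whose
predictions best match the supplied empirical probabilities (least squares).
With ``y=None`` the declared parameters are adopted unchanged, so the
estimator also works as a fixed, training-free model inside sklearn
pipelines and model selection.
"""

from __future__ import annotations

import itertools

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .network import TwoStageNetwork
from .predictor import (
    MAGNITUDE_MODES,
    NORMALIZATION_MODES,
    SCOPE_MODES,
    PredictorConfig,
    beqbn_predict,
    cbn_predict,
)

__all__ = ["ClassicalNetworkPredictor", "QuantumLikePredictor", "networks_to_array"]


def networks_to_array(networks) -> np.ndarray:
    """Stack ``TwoStageNetwork`` objects into an (n, 3) feature array."""
    return np.array(
        [[n.p_a1, n.p_b1_given_a1, n.p_b1_given_a2] for n in networks], dtype=float
    )


def _validate_networks(X) -> list[TwoStageNetwork]:
    X = check_array(X, dtype=float, ensure_min_features=3)
    if X.shape[1] != 3:
        raise ValueError(f"X must have exactly 3 columns, got {X.shape[1]}")
    return [TwoStageNetwork(*row) for row in X]


class ClassicalNetworkPredictor(BaseEstimator, RegressorMixin):
    """Total-probability-law baseline as a (stateless) sklearn estimator.

    Parameters
    ----------
    outcome : {"b1", "b2"}
        Child outcome whose marginal probability ``predict`` returns.
    """

    def __init__(self, outcome: str = "b1"):
        self.outcome = outcome

    def fit(self, X, y=None):
        _validate_networks(X)
        self.n_features_in_ = 3
        self.is_fitted_ = True
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self)
        nets = _validate_networks(X)
        return np.array([cbn_predict(n, self.outcome) for n in nets])


class QuantumLikePredictor(BaseEstimator, RegressorMixin):
    """Biased entangled quantum-like predictor as an sklearn estimator.

    Parameters
    ----------
    interference_magnitude : {"born_cross_term", "literal_product"}
    normalization : {"clamp", "sum_normalize"}
    entanglement_scope : {"queried_outcome", "per_outcome"}
        See :class:`beqbn.predictor.PredictorConfig`.
    n_witness : int
        Harmonic order of the witness-to-concurrence map (default 16).
    outcome : {"b1", "b2"}
        Child outcome whose probability ``predict`` returns.
    calibrate_modes : bool
        When True and ``fit`` receives targets ``y``, enumerate all mode
        combinations and keep the least-squares best; when False, ``fit``
        only validates and adopts the declared modes.

    Attributes
    ----------
    config_ : PredictorConfig
        Modes in effect after ``fit``.
    calibration_report_ : list of dict or None
        Per-candidate mean squared error when calibration ran.
    """

    def __init__(
        self,
        interference_magnitude: str = "born_cross_term",
        normalization: str = "clamp",
        entanglement_scope: str = "queried_outcome",
        n_witness: int = 16,
        outcome: str = "b1",
        calibrate_modes: bool = True,
    ):
        self.interference_magnitude = interference_magnitude
        self.normalization = normalization
        self.entanglement_scope = entanglement_scope
        self.n_witness = n_witness
        self.outcome = outcome
        self.calibrate_modes = calibrate_modes

    def _declared_config(self) -> PredictorConfig:
        return PredictorConfig(
            interference_magnitude=self.interference_magnitude,
            normalization=self.normalization,
            entanglement_scope=self.entanglement_scope,
            n_witness=self.n_witness,
        )

    def fit(self, X, y=None):
        nets = _validate_networks(X)
        self.n_features_in_ = 3
        if y is None or not self.calibrate_modes:
            self.config_ = self._declared_config()
            self.calibration_report_ = None
            return self
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != len(nets):
            raise ValueError("X and y have inconsistent lengths")
        report = []
        for mag, norm, scope in itertools.product(
            MAGNITUDE_MODES, NORMALIZATION_MODES, SCOPE_MODES
        ):
            cfg = PredictorConfig(mag, norm, scope, self.n_witness)
            pred = np.array(
                [beqbn_predict(n, self.outcome, cfg).probability for n in nets]
            )
            report.append(
                {"config": cfg.as_dict(), "mse": float(np.mean((pred - y) ** 2))}
            )
        best = min(range(len(report)), key=lambda i: report[i]["mse"])
        self.config_ = PredictorConfig(
            report[best]["config"]["interference_magnitude"],
            report[best]["config"]["normalization"],
            report[best]["config"]["entanglement_scope"],
            self.n_witness,
        )
        self.calibration_report_ = report
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self)
        nets = _validate_networks(X)
        return np.array(
            [beqbn_predict(n, self.outcome, self.config_).probability for n in nets]
        )

    def predict_breakdown(self, X) -> list:
        """Full :class:`PredictionBreakdown` for each row of ``X``."""
        check_is_fitted(self)
        nets = _validate_networks(X)
        return [beqbn_predict(n, self.outcome, self.config_) for n in nets]
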