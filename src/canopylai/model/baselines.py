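"""Comparison models: transformer, KNN, MLP, CNN, RF, XGBoost.

All baselines consume the same normalized inputs as the hybrid; the
classical models see them flattened to one vector per sample. The CNN
baseline is exactly the hybrid's CNN branch plus its dense head; the
transformer is the in-package encoder. KNN/MLP/RF/XGBoost wrap the
corresponding scikit-learn / xgboost estimators with documented
defaults: KNN k=5 distance-weighted, RF 500 trees, XGBoost 500 rounds at
learning rate 0.05 and depth 6, MLP hidden layers (128, 64).
"""

from __future__ import annotations

import numpy as np

from canopylai.model.networks import (
    CNNGRURegressor,
    CNNRegressor,
    ModelConfig,
    TransformerRegressor,
)

__all__ = ["BASELINE_NAMES", "SklearnAdapter", "build_baseline"]

BASELINE_NAMES = ("transformer", "knn", "mlp", "cnn", "rf", "xgboost")


def _flatten(inputs: dict[str, np.ndarray]) -> np.ndarray:
    key = "matrix" if "matrix" in inputs else "image"
    arr = inputs[key]
    return arr.reshape(len(arr), -1)


class SklearnAdapter:
    """Gives estimator-style models the dict-input fit/predict surface."""

    def __init__(self, name: str, estimator):
        self.name = name
        self.estimator = estimator
        self.history: list[dict] = []

    def fit(self, inputs: dict[str, np.ndarray], y: np.ndarray) -> "SklearnAdapter":
        self.estimator.fit(_flatten(inputs), np.asarray(y, dtype=float))
        return self

    def predict(self, inputs: dict[str, np.ndarray]) -> np.ndarray:
        return np.asarray(self.estimator.predict(_flatten(inputs)), dtype=float)

    def n_parameters(self) -> int:  # not meaningful for instance/tree models
        return 0


def build_baseline(name: str, config: ModelConfig, **overrides):
    """Construct an untrained baseline by name.

    ``overrides`` pass straight to the underlying estimator for the
    scikit-learn/xgboost-backed models (e.g. ``n_neighbors=1``,
    ``n_estimators=1``).
    """
    name = name.lower()
    if name == "cnn":
        return CNNRegressor(config)
    if name == "cnn_gru":
        return CNNGRURegressor(config)
    if name == "transformer":
        return TransformerRegressor(config)
    if name == "knn":
        from sklearn.neighbors import KNeighborsRegressor

        params = dict(n_neighbors=5, weights="distance")
        params.update(overrides)
        return SklearnAdapter(name, KNeighborsRegressor(**params))
    if name == "mlp":
        from sklearn.neural_network import MLPRegressor

        params = dict(
            hidden_layer_sizes=(128, 64),
            max_iter=2000,
            learning_rate_init=0.01,
            tol=1e-7,
            random_state=config.seed,
        )
        params.update(overrides)
        return SklearnAdapter(name, MLPRegressor(**params))
    if name == "rf":
        from sklearn.ensemble import RandomForestRegressor

        params = dict(n_estimators=500, random_state=config.seed)
        params.update(overrides)
        return SklearnAdapter(name, RandomForestRegressor(**params))
    if name == "xgboost":
        from xgboost import XGBRegressor

        params = dict(
            n_estimators=500,
            learning_rate=0.05,
            max_depth=6,
            random_state=config.seed,
            n_jobs=1,
        )
        params.update(overrides)
        return SklearnAdapter(name, XGBRegressor(**params))
    raise KeyError(f"unknown baseline {name!r}; choose from {BASELINE_NAMES}")
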