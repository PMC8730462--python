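"""One-step-ahead SpO2 forecasters (sklearn-style estimators).

``LSTMForecaster`` is the recurrent network described in the methods
note: batch-normalized lag inputs feed a shallow (2-layer) or deep
(5-layer) LSTM stack with dropout and a single linear output unit,
trained on transformed SpO2 with MSE loss, Adam, a per-epoch random
validation holdout and best-epoch weight restoration.
``PersistenceForecaster`` is the naive baseline that predicts the next
value equals the most recent observation. ``cross_validate`` runs the
3-fold grid search over {shallow, deep} x {0.001, 0.01, 0.1}.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import GroupKFold, KFold
from sklearn.utils.validation import check_is_fitted, validate_data

from ._nn import SequenceRegressor, fit_model
from .series import SupervisedDataset, TransformedSeries

__all__ = [
    "LSTMForecaster",
    "PersistenceForecaster",
    "CVResult",
    "cross_validate",
    "default_grid",
    "save_model",
    "load_model",
]

SHALLOW_WIDTHS = (256, 16)
DEEP_WIDTHS = (256, 128, 64, 32, 16)

MODEL_FORMAT = "spo2cast-lstm/1"


class PersistenceForecaster(RegressorMixin, BaseEstimator):
    """Naive baseline: the next value equals the most recent lag."""

    def fit(self, X, y=None):
        X = validate_data(self, X)
        self.is_fitted_ = True
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return X[:, -1]

    def predict_series(self, series: TransformedSeries, lags: int = 2):
        p = series.p_values
        if p.size <= lags:
            return np.empty(0)
        return p[lags - 1 : -1].copy()


class LSTMForecaster(RegressorMixin, BaseEstimator):
    """Recurrent one-step-ahead regressor on transformed SpO2 lags.

    Parameters
    ----------
    architecture : {"shallow", "deep"}
        Shallow uses 2 LSTM layers (default widths 256 and 16), deep uses
        5 layers (default taper 256/128/64/32/16).
    lags : int
        Number of prior timepoints per input row (default 2).
    horizon_minutes : {5, 30}
        Sampling interval of the series the model is meant for; purely a
        bookkeeping tag checked by :meth:`predict_series`.
    lstm_widths : sequence of int, optional
        Explicit layer widths; length must match the architecture's layer
        count (2 or 5). Smaller widths keep CPU training cheap.
    dropout : float
        Dropout rate applied after every LSTM layer (default 0.1).
    learning_rate : float
        Adam learning rate (default 0.001).
    epochs, validation_fraction, batch_size : training loop controls.
        Each epoch holds out a random ``validation_fraction`` of rows;
        weights are restored from the epoch with lowest validation loss.
    resplit_validation : bool
        Re-draw the validation split every epoch (the literal protocol);
        False fixes one seeded split, making best-epoch selection less
        noisy.
    seed : int
        Controls initialization, dropout masks and the split/shuffle
        stream; fixed seed gives bit-reproducible training.
    """

    def __init__(
        self,
        architecture: str = "shallow",
        lags: int = 2,
        horizon_minutes: float = 5,
        lstm_widths=None,
        dropout: float = 0.1,
        learning_rate: float = 0.001,
        epochs: int = 100,
        validation_fraction: float = 0.1,
        batch_size: int = 256,
        resplit_validation: bool = True,
        seed: int = 0,
    ):
        self.architecture = architecture
        self.lags = lags
        self.horizon_minutes = horizon_minutes
        self.lstm_widths = lstm_widths
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.validation_fraction = validation_fraction
        self.batch_size = batch_size
        self.resplit_validation = resplit_validation
        self.seed = seed

    def _resolved_widths(self):
        n_layers = {"shallow": 2, "deep": 5}.get(self.architecture)
        if n_layers is None:
            raise ValueError("architecture must be 'shallow' or 'deep'")
        widths = self.lstm_widths
        if widths is None:
            widths = SHALLOW_WIDTHS if self.architecture == "shallow" else DEEP_WIDTHS
        widths = tuple(int(w) for w in widths)
        if len(widths) != n_layers:
            raise ValueError(
                f"{self.architecture} architecture requires {n_layers} LSTM "
                f"layers, got widths {widths}"
            )
        return widths

    def _validate_config(self):
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.lags < 1 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("lags, epochs and batch_size must be >= 1")

    def fit(self, X, y):
        """Train on a lag matrix X (n, lags) and next-step targets y."""
        self._validate_config()
        X, y = validate_data(self, X, y)
        if X.shape[1] != self.lags:
            raise ValueError(f"X has {X.shape[1]} columns, expected lags={self.lags}")
        widths = self._resolved_widths()
        model = SequenceRegressor(self.lags, widths, dropout=self.dropout, seed=self.seed)
        history, best_epoch = fit_model(
            model,
            X,
            y,
            epochs=self.epochs,
            batch_size=self.batch_size,
            validation_fraction=self.validation_fraction,
            learning_rate=self.learning_rate,
            seed=self.seed,
            resplit_validation=self.resplit_validation,
        )
        self.model_ = model
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.lstm_widths_ = widths
        return self

    def predict(self, X):
        """One-step-ahead predictions, clipped into the valid p range [0, 1)."""
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return np.clip(self.model_.predict(X), 0.0, np.nextafter(1.0, 0.0))

    def predict_series(self, series: TransformedSeries):
        """Teacher-forced waveform prediction for one preprocessed stay.

        Every input row uses observed prior values (no recursive
        rollout); the output aligns with indices ``lags..end`` of the
        series. A series shorter than lags+1 yields an empty prediction.
        """
        check_is_fitted(self)
        if series.interval_minutes != self.horizon_minutes:
            raise ValueError(
                f"series at {series.interval_minutes}-minute intervals does not "
                f"match the model horizon of {self.horizon_minutes} minutes"
            )
        p = series.p_values
        if p.size <= self.lags:
            warnings.warn(f"stay {series.stay_id}: too short to predict", stacklevel=2)
            return np.empty(0)
        n = p.size
        X = np.column_stack([p[k : n - self.lags + k] for k in range(self.lags)])
        return self.predict(X)


@dataclass
class CVResult:
    """Grid-search record: per-fold MSE and the selected candidate."""

    grid: list
    fold_mse: np.ndarray  # (n_candidates, n_folds)
    selected: tuple
    mean_mse: np.ndarray = field(init=False)

    def __post_init__(self):
        self.fold_mse = np.asarray(self.fold_mse, dtype=float)
        self.mean_mse = self.fold_mse.mean(axis=1)


def default_grid():
    """The hyperparameter grid: 2 architectures x 3 Adam learning rates."""
    return [(arch, lr) for arch in ("shallow", "deep") for lr in (0.001, 0.01, 0.1)]


def cross_validate(
    dataset: SupervisedDataset,
    grid=None,
    folds: int = 3,
    stay_level: bool = False,
    seed: int = 0,
    **config,
) -> CVResult:
    """K-fold grid search; selects the lowest mean held-out MSE.

    Folds are drawn over pooled rows by default (matching training on the
    concatenated cohort vector); ``stay_level=True`` keeps each stay's
    rows in a single fold to avoid within-stay leakage. Extra keyword
    arguments (e.g. ``epochs``, ``lstm_widths``) are forwarded to every
    candidate ``LSTMForecaster``.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if grid is None:
        grid = default_grid()
    X, Y = dataset.X, dataset.Y
    if stay_level:
        groups = np.empty(len(dataset), dtype=int)
        for gi, (_, start, stop) in enumerate(dataset.stay_boundaries):
            groups[start:stop] = gi
        splits = list(GroupKFold(n_splits=folds).split(X, Y, groups))
    else:
        splits = list(KFold(n_splits=folds, shuffle=True, random_state=seed).split(X))
    config.setdefault("lags", dataset.lags)
    fold_mse = np.empty((len(grid), len(splits)))
    for ci, (arch, lr) in enumerate(grid):
        widths = config.get("lstm_widths")
        if widths is not None and len(widths) != (2 if arch == "shallow" else 5):
            # width override applies per-architecture; fall back to defaults
            cand_cfg = {k: v for k, v in config.items() if k != "lstm_widths"}
        else:
            cand_cfg = config
        for fi, (tr, te) in enumerate(splits):
            est = LSTMForecaster(
                architecture=arch, learning_rate=lr, seed=seed, **cand_cfg
            )
            try:
                est.fit(X[tr], Y[tr])
                pred = est.predict(X[te])
                fold_mse[ci, fi] = float(np.mean((pred - Y[te]) ** 2))
            except RuntimeError:
                # divergent training (e.g. lr 0.1) scores as infinitely bad
                fold_mse[ci, fi] = np.inf
    selected = grid[int(np.argmin(fold_mse.mean(axis=1)))]
    return CVResult(grid=list(grid), fold_mse=fold_mse, selected=selected)


def save_model(trained: LSTMForecaster, path) -> None:
    """Serialize a fitted forecaster to a single .npz archive.

    The archive holds every weight array plus a JSON header with the
    format tag, estimator parameters, training history and best epoch.
    """
    check_is_fitted(trained)
    state = trained.model_.get_state()
    arrays = {}
    for li, layer_params in enumerate(state["params"]):
        for name, value in layer_params.items():
            arrays[f"layer{li}:{name}"] = value
    arrays["running_mean"] = state["running_mean"]
    arrays["running_var"] = state["running_var"]
    meta = {
        "format": MODEL_FORMAT,
        "params": trained.get_params(),
        "history": trained.history_,
        "best_epoch": trained.best_epoch_,
        "widths": list(trained.lstm_widths_),
    }
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path) -> LSTMForecaster:
    """Load a forecaster saved by :func:`save_model`."""
    try:
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            arrays = {k: data[k] for k in data.files if k != "meta"}
    except (OSError, ValueError, KeyError, json.JSONDecodeError) as exc:
        raise ValueError(f"not a readable model file: {path}") from exc
    if meta.get("format") != MODEL_FORMAT:
        raise ValueError(
            f"unsupported model format {meta.get('format')!r}; "
            f"expected {MODEL_FORMAT!r}"
        )
    params = dict(meta["params"])
    if params.get("lstm_widths") is not None:
        params["lstm_widths"] = tuple(params["lstm_widths"])  # JSON gives lists
    est = LSTMForecaster(**params)
    model = SequenceRegressor(est.lags, meta["widths"], dropout=est.dropout, seed=est.seed)
    state = model.get_state()
    for li, layer_params in enumerate(state["params"]):
        for name in layer_params:
            layer_params[name] = arrays[f"layer{li}:{name}"]
    state["running_mean"] = arrays["running_mean"]
    state["running_var"] = arrays["running_var"]
    model.set_state(state)
    est.model_ = model
    est.history_ = meta["history"]
    est.best_epoch_ = meta["best_epoch"]
    est.lstm_widths_ = tuple(meta["widths"])
    est.n_features_in_ = est.lags
    return est
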