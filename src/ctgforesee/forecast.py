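"""LSTM forecasting of FHR and UC signals.

One forecaster is trained per recording and channel, in the
statsmodels idiom: :class:`LSTMForecaster` is built from the raw series
and a :class:`ForecastModelSpec`; ``fit()`` returns a
:class:`ForecastResults` holding the trained network, one-step test
errors, recursive validation errors and a ``summary()`` table.

Protocol: the final 480 samples (2 min at 4 Hz) are held out for
validation; the remaining prefix is split 80/20 chronologically into
training and testing windows.  The series is smoothed (moving average)
and standardized with training-split statistics; reported errors are
destandardized back to signal units.  Validation is *recursive*: the
model rolls forward one step at a time, feeding each prediction back
into its window — the same regime used to forecast the future of a live
recording — while test errors are one-step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import ParameterError, SmoothingConfig, smooth as smooth_series
from .lstm import LSTMNet

VALIDATION_STEPS = 480  # 2 min at 4 Hz

__all__ = [
    "VALIDATION_STEPS",
    "ForecastModelSpec",
    "ForecastReport",
    "LSTMForecaster",
    "ForecastResults",
    "make_supervised",
    "split_series",
    "build_forecaster",
    "train_forecaster",
    "forecast_recursive",
    "rmse_mae",
    "fhr_acidosis_spec",
    "uc_acidosis_spec",
    "fhr_non_acidosis_spec",
    "uc_non_acidosis_spec",
    "fast_spec",
]


@dataclass(frozen=True)
class ForecastModelSpec:
    """Architecture and training hyperparameters of one forecaster.

    ``layers`` is the ordered stack after the input window: ``("lstm",
    units)`` exactly once and first, optionally ``("dropout", rate)``,
    then ``("dense", width)`` entries ending in width 1.
    """

    lookback: int = 64
    layers: tuple[tuple[str, float], ...] = (
        ("lstm", 10),
        ("dropout", 0.1),
        ("dense", 1),
    )
    optimizer: str = "sgd"
    learning_rate: float = 0.01
    momentum: float = 0.9
    loss: str = "mean_squared_error"
    epochs: int = 30
    batch_size: int = 64
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lookback < 1:
            raise ParameterError("lookback must be >= 1")
        if self.optimizer != "sgd":
            raise ParameterError("only the SGD optimizer is supported")
        if self.loss != "mean_squared_error":
            raise ParameterError("only mean_squared_error loss is supported")
        if not self.layers or self.layers[0][0] != "lstm":
            raise ParameterError("layer stack must start with an lstm layer")
        tail = self.layers[1:]
        if any(kind == "lstm" for kind, _ in tail):
            raise ParameterError("only one lstm layer is supported")
        dense = [v for kind, v in tail if kind == "dense"]
        if not dense or dense[-1] != 1:
            raise ParameterError("layer stack must end with a width-1 dense layer")
        for kind, v in tail:
            if kind == "dropout" and not (0.0 <= v < 1.0):
                raise ParameterError("dropout rates must lie in [0, 1)")
            if kind not in ("dropout", "dense"):
                raise ParameterError(f"unknown layer kind {kind!r}")


# Printed per-record architectures (lookbacks 1500/2000/1000/800).
def fhr_acidosis_spec(**kw) -> ForecastModelSpec:
    return replace(
        ForecastModelSpec(
            lookback=1500,
            layers=(("lstm", 10), ("dropout", 0.1), ("dense", 2), ("dense", 1)),
        ),
        **kw,
    )


def uc_acidosis_spec(**kw) -> ForecastModelSpec:
    return replace(
        ForecastModelSpec(
            lookback=2000, layers=(("lstm", 10), ("dropout", 0.1), ("dense", 1))
        ),
        **kw,
    )


def fhr_non_acidosis_spec(**kw) -> ForecastModelSpec:
    return replace(
        ForecastModelSpec(lookback=1000, layers=(("lstm", 10), ("dense", 1))), **kw
    )


def uc_non_acidosis_spec(**kw) -> ForecastModelSpec:
    return replace(
        ForecastModelSpec(
            lookback=800, layers=(("lstm", 10), ("dropout", 0.1), ("dense", 1))
        ),
        **kw,
    )


def fast_spec(**kw) -> ForecastModelSpec:
    """Desk-scale profile: lookback 64, one LSTM(10) + dense(1)."""
    return replace(
        ForecastModelSpec(lookback=64, layers=(("lstm", 10), ("dense", 1))), **kw
    )


@dataclass
class ForecastReport:
    """Errors in original signal units; RMSE >= MAE on each residual set."""

    testing_rmse: float
    testing_mae: float
    validation_rmse: float
    validation_mae: float

    def __post_init__(self) -> None:
        for name in ("testing", "validation"):
            rmse = getattr(self, f"{name}_rmse")
            mae = getattr(self, f"{name}_mae")
            if not (rmse >= mae >= 0.0 or np.isnan(rmse)):
                raise ParameterError(f"{name} errors violate RMSE >= MAE >= 0")

    def as_dict(self) -> dict[str, float]:
        return {
            "testing_rmse": self.testing_rmse,
            "testing_mae": self.testing_mae,
            "validation_rmse": self.validation_rmse,
            "validation_mae": self.validation_mae,
        }


# ---------------------------------------------------------------------------
# supervised framing
# ---------------------------------------------------------------------------


def make_supervised(series: np.ndarray, lookback: int) -> tuple[np.ndarray, np.ndarray]:
    """Sliding (window, next value) pairs in chronological order.

    Returns ``X`` of shape (n - lookback, lookback) and targets ``t`` of
    length n - lookback, where pair ``i`` is (samples [i, i+lookback),
    sample i+lookback).
    """
    x = np.asarray(series, dtype=float)
    if len(x) <= lookback:
        raise ParameterError(
            f"series length {len(x)} must exceed lookback {lookback}"
        )
    n_pairs = len(x) - lookback
    X = np.lib.stride_tricks.sliding_window_view(x, lookback)[:n_pairs]
    return X.copy(), x[lookback:].copy()


def split_series(
    series: np.ndarray,
    validation_steps: int = VALIDATION_STEPS,
    lookback: int = 1,
    train_frac: float = 0.8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Chronological (train, test, validation) split of one series.

    Validation is the final ``validation_steps`` samples; the remaining
    prefix is split ``train_frac`` / ``1 - train_frac`` in time order.
    """
    x = np.asarray(series, dtype=float)
    if len(x) <= validation_steps + lookback + 10:
        raise ParameterError(
            f"series of length {len(x)} too short for validation_steps="
            f"{validation_steps} with lookback {lookback}"
        )
    prefix = x[: len(x) - validation_steps]
    n_train = int(len(prefix) * train_frac)
    return prefix[:n_train], prefix[n_train:], x[len(x) - validation_steps :]


def build_forecaster(spec: ForecastModelSpec) -> LSTMNet:
    """Instantiate the network described by a spec (weights seeded)."""
    hidden = int(spec.layers[0][1])
    dropout = 0.0
    dense: list[int] = []
    for kind, v in spec.layers[1:]:
        if kind == "dropout":
            if dense:
                raise ParameterError("dropout must precede the dense head")
            dropout = float(v)
        else:
            dense.append(int(v))
    return LSTMNet(
        in_dim=spec.lookback,
        hidden=hidden,
        dense=tuple(dense),
        dropout=dropout,
        seed=spec.seed,
    )


def rmse_mae(predicted: np.ndarray, actual: np.ndarray) -> tuple[float, float]:
    """Root-mean-square and mean-absolute error of a prediction."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.size == 0:
        raise ParameterError("predicted and actual must be equal-length, nonempty")
    resid = p - a
    return float(np.sqrt(np.mean(resid**2))), float(np.mean(np.abs(resid)))


def forecast_recursive(
    model: "LSTMNet | object",
    history: np.ndarray,
    horizon: int,
    mean: float = 0.0,
    std: float = 1.0,
) -> np.ndarray:
    """Recursive multi-step forecast in original signal units.

    ``history`` is in original units; it is standardized with the given
    moments, the model iterates one-step predictions (each appended to
    its own window), and the trajectory is destandardized.  The model
    must expose ``predict`` over windows of length ``in_dim``.
    """
    if horizon <= 0:
        raise ParameterError("horizon must be positive")
    lookback = getattr(model, "in_dim")
    h = (np.asarray(history, dtype=float) - mean) / std
    if len(h) < lookback:
        raise ParameterError("history shorter than the model lookback")
    window = h[-lookback:].copy()
    out = np.empty(horizon)
    for k in range(horizon):
        nxt = float(model.predict(window[None, :])[0])
        out[k] = nxt
        window[:-1] = window[1:]
        window[-1] = nxt
    return out * std + mean


# ---------------------------------------------------------------------------
# model / results front end
# ---------------------------------------------------------------------------


class LSTMForecaster:
    """Per-recording, per-channel LSTM forecaster (model object).

    Parameters
    ----------
    series : ndarray
        The raw channel samples at 4 Hz, in original units.
    spec : ForecastModelSpec
        Architecture + training hyperparameters.
    smoothing : SmoothingConfig or None
        Moving-average pre-smoothing; ``None`` disables it.
    """

    def __init__(
        self,
        series: np.ndarray,
        spec: ForecastModelSpec | None = None,
        smoothing: SmoothingConfig | None = SmoothingConfig(),
        validation_steps: int = VALIDATION_STEPS,
    ):
        self.raw = np.asarray(series, dtype=float)
        if not np.isfinite(self.raw).all():
            raise ParameterError("forecaster input must be gap-free and finite")
        self.spec = spec or fast_spec()
        self.smoothing = smoothing
        self.validation_steps = validation_steps
        self.series = (
            smooth_series(self.raw, smoothing) if smoothing is not None else self.raw
        )

    def fit(self, verbose: bool = False) -> "ForecastResults":
        """Train with mini-batch SGD and early stopping on test loss."""
        spec = self.spec
        train, test, validation = split_series(
            self.series, self.validation_steps, spec.lookback
        )
        mean = float(np.mean(train))
        sd = float(np.std(train))
        if sd < 1e-8:
            sd = 1.0  # constant series: center only
        z = (self.series - mean) / sd
        prefix = z[: len(z) - self.validation_steps]
        X, t = make_supervised(prefix, spec.lookback)
        n_train_targets = len(train) - spec.lookback
        if n_train_targets < 1:
            raise ParameterError("training split shorter than the lookback")
        Xtr, ttr = X[:n_train_targets], t[:n_train_targets]
        Xte, tte = X[n_train_targets:], t[n_train_targets:]
        net = build_forecaster(spec)
        rng = np.random.default_rng(spec.seed + 1)
        best_loss, best_weights, stale = np.inf, net.get_weights(), 0
        history: list[tuple[float, float]] = []
        for epoch in range(spec.epochs):
            order = rng.permutation(len(Xtr))
            epoch_loss = 0.0
            for start in range(0, len(order), spec.batch_size):
                idx = order[start : start + spec.batch_size]
                loss = net.train_batch(
                    Xtr[idx], ttr[idx], spec.learning_rate, spec.momentum, rng
                )
                if not np.isfinite(loss):
                    raise ParameterError(
                        f"training diverged (loss not finite) at epoch {epoch + 1}"
                    )
                epoch_loss += loss * len(idx)
            epoch_loss /= len(Xtr)
            test_loss = (
                float(np.mean((net.predict(Xte) - tte) ** 2)) if len(Xte) else epoch_loss
            )
            history.append((epoch_loss, test_loss))
            if verbose:
                print(f"epoch {epoch + 1:3d}  train {epoch_loss:.5f}  test {test_loss:.5f}")
            if test_loss < best_loss - 1e-9:
                best_loss, best_weights, stale = test_loss, net.get_weights(), 0
            else:
                stale += 1
                if stale >= spec.patience:
                    break
        net.set_weights(best_weights)

        test_pred = net.predict(Xte) * sd + mean if len(Xte) else np.array([])
        test_act = tte * sd + mean
        t_rmse, t_mae = (
            rmse_mae(test_pred, test_act) if len(Xte) else (float("nan"),) * 2
        )
        val_pred = forecast_recursive(
            net, self.series[: len(self.series) - self.validation_steps],
            self.validation_steps, mean, sd,
        )
        v_rmse, v_mae = rmse_mae(val_pred, validation)
        report = ForecastReport(t_rmse, t_mae, v_rmse, v_mae)
        return ForecastResults(
            model=self, net=net, mean=mean, std=sd, report=report,
            validation_forecast=val_pred, history=history,
        )


@dataclass
class ForecastResults:
    """A trained forecaster plus its error report."""

    model: LSTMForecaster
    net: LSTMNet
    mean: float
    std: float
    report: ForecastReport
    validation_forecast: np.ndarray = field(repr=False)
    history: list = field(repr=False, default_factory=list)

    def forecast(self, horizon: int, history: np.ndarray | None = None) -> np.ndarray:
        """Recursive forecast from the end of ``history`` (default: the
        fitted series), in original units."""
        h = self.model.series if history is None else np.asarray(history, dtype=float)
        return forecast_recursive(self.net, h, horizon, self.mean, self.std)

    def plot(self, ax=None):
        """Plot the validation hold-out against the recursive forecast."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        actual = self.model.series[-self.model.validation_steps :]
        t = np.arange(len(actual)) / 4.0
        ax.plot(t, actual, label="observed", lw=1.2)
        ax.plot(t, self.validation_forecast, label="recursive forecast", lw=1.2)
        ax.set_xlabel("time into hold-out (s)")
        ax.set_ylabel("signal")
        ax.legend(frameon=False)
        return ax

    def summary(self) -> str:
        spec = self.model.spec
        stack = " -> ".join(f"{k}({v:g})" for k, v in spec.layers)
        lines = [
            "LSTM forecaster",
            "=" * 48,
            f"lookback          {spec.lookback}",
            f"stack             {stack}",
            f"optimizer         sgd(lr={spec.learning_rate}, momentum={spec.momentum})",
            f"epochs run        {len(self.history)} (batch {spec.batch_size})",
            f"testing RMSE      {self.report.testing_rmse:.4f}",
            f"testing MAE       {self.report.testing_mae:.4f}",
            f"validation RMSE   {self.report.validation_rmse:.4f}",
            f"validation MAE    {self.report.validation_mae:.4f}",
        ]
        return "\n".join(lines)


def train_forecaster(
    series: np.ndarray,
    spec: ForecastModelSpec,
    smoothing: SmoothingConfig | None = SmoothingConfig(),
) -> tuple[LSTMNet, ForecastReport, ForecastResults]:
    """Functional wrapper: train and return (net, report, full results)."""
    res = LSTMForecaster(series, spec, smoothing).fit()
    return res.net, res.report, res
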