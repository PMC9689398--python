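"""A small LSTM regression network in NumPy.

The forecasting architectures used here feed each lookback window to the
network as a *single* timestep whose feature vector is the whole window
(input shape ``(batch, 1, lookback)``), so the LSTM cell runs exactly
once per window, acting as a gated projection of the window.  That makes
exact manual backpropagation small and fast — no unrolling over time is
needed for training, while the generic cell below still supports
arbitrary sequences for inspection and testing.

Cell equations, for input ``x_t``, previous output ``y_{t-1}`` and
previous cell state ``C_{t-1}`` (``U`` input weights, ``W`` recurrent
weights, no gate biases):

    f_t = sigmoid(x_t U^f + y_{t-1} W^f)        forget gate
    i_t = sigmoid(x_t U^i + y_{t-1} W^i)        input gate
    g_t = tanh   (x_t U^g + y_{t-1} W^g)        candidate state
    o_t = sigmoid(x_t U^o + y_{t-1} W^o)        output gate
    C_t = f_t * C_{t-1} + i_t * g_t
    y_t = tanh(C_t) * o_t

The dense head applies affine layers (with biases) on top of ``y_t``;
an optional inverted-dropout layer regularises the cell output during
training.  Training is mini-batch SGD (with optional momentum) on mean
squared error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ParameterError

__all__ = ["LSTMCellParams", "lstm_cell_step", "LSTMNet"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


@dataclass
class LSTMCellParams:
    """Weights of one LSTM cell: input matrices U and recurrent W per gate."""

    U_f: np.ndarray
    U_i: np.ndarray
    U_g: np.ndarray
    U_o: np.ndarray
    W_f: np.ndarray
    W_i: np.ndarray
    W_g: np.ndarray
    W_o: np.ndarray

    @classmethod
    def init(cls, rng: np.random.Generator, in_dim: int, hidden: int) -> "LSTMCellParams":
        return cls(
            *(_glorot(rng, in_dim, hidden) for _ in range(4)),
            *(_glorot(rng, hidden, hidden) for _ in range(4)),
        )

    @property
    def hidden(self) -> int:
        return self.U_f.shape[1]


def lstm_cell_step(
    x_t: np.ndarray,
    y_prev: np.ndarray,
    c_prev: np.ndarray,
    params: LSTMCellParams,
) -> dict[str, np.ndarray]:
    """One cell step; returns all gate activations and the new state.

    Guarantees by construction: ``f, i, o`` lie in (0, 1); the candidate
    ``g`` in (-1, 1); ``C_t = f*C_prev + i*g``; ``y_t = tanh(C_t)*o``.
    """
    f = _sigmoid(x_t @ params.U_f + y_prev @ params.W_f)
    i = _sigmoid(x_t @ params.U_i + y_prev @ params.W_i)
    g = np.tanh(x_t @ params.U_g + y_prev @ params.W_g)
    o = _sigmoid(x_t @ params.U_o + y_prev @ params.W_o)
    c = f * c_prev + i * g
    y = np.tanh(c) * o
    return {"f": f, "i": i, "g": g, "o": o, "c": c, "y": y}


class LSTMNet:
    """LSTM cell + dropout + dense head, for single-timestep windows.

    Parameters
    ----------
    in_dim : int
        Window length (the lookback), fed as one timestep.
    hidden : int
        Number of LSTM cells.
    dense : tuple of int
        Widths of the affine layers after the cell; must end in 1.
    dropout : float
        Inverted-dropout rate on the cell output during training.
    seed : int
        Weight-initialisation seed (Glorot uniform).
    """

    def __init__(
        self,
        in_dim: int,
        hidden: int = 10,
        dense: tuple[int, ...] = (1,),
        dropout: float = 0.0,
        seed: int = 0,
    ):
        if not dense or dense[-1] != 1:
            raise ParameterError("dense stack must end in a width-1 layer")
        if not (0.0 <= dropout < 1.0):
            raise ParameterError("dropout rate must lie in [0, 1)")
        self.in_dim, self.hidden, self.dropout = in_dim, hidden, dropout
        rng = np.random.default_rng(seed)
        self.cell = LSTMCellParams.init(rng, in_dim, hidden)
        self.dense_W: list[np.ndarray] = []
        self.dense_b: list[np.ndarray] = []
        prev = hidden
        for width in dense:
            self.dense_W.append(_glorot(rng, prev, width))
            self.dense_b.append(np.zeros(width))
            prev = width
        self._params = [
            self.cell.U_i, self.cell.U_g, self.cell.U_o,
            *self.dense_W, *self.dense_b,
        ]
        self._velocity = [np.zeros_like(p) for p in self._params]

    # -- forward -----------------------------------------------------------

    def forward(
        self, X: np.ndarray, train_rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, dict]:
        """Predict a scalar per window; returns (outputs, cache).

        ``train_rng`` enables inverted dropout (training mode); the cache
        holds the intermediates needed by :meth:`backward`.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        zeros = np.zeros((X.shape[0], self.hidden))
        gates = lstm_cell_step(X, zeros, zeros, self.cell)
        h = gates["y"]
        if train_rng is not None and self.dropout > 0.0:
            mask = (train_rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
        else:
            mask = np.ones_like(h)
        a = h * mask
        activations = [a]
        for W, b in zip(self.dense_W, self.dense_b):
            a = a @ W + b
            activations.append(a)
        cache = {"X": X, "gates": gates, "mask": mask, "activations": activations}
        return a[:, 0], cache

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    # -- backward ----------------------------------------------------------

    def _gradients(self, cache: dict, dout: np.ndarray) -> list[np.ndarray]:
        """Exact gradients of the loss w.r.t. every trainable parameter.

        With a single timestep and zero initial state the forget gate
        multiplies ``C_prev = 0`` and the recurrent matrices multiply
        ``y_prev = 0``, so neither receives gradient; the trainable set
        is U^i, U^g, U^o and the dense weights/biases.
        """
        X, gates, mask = cache["X"], cache["gates"], cache["mask"]
        acts = cache["activations"]
        grad_W: list[np.ndarray] = [None] * len(self.dense_W)
        grad_b: list[np.ndarray] = [None] * len(self.dense_b)
        da = dout[:, None]  # gradient flowing into the last activation
        for k in range(len(self.dense_W) - 1, -1, -1):
            grad_W[k] = acts[k].T @ da
            grad_b[k] = da.sum(axis=0)
            da = da @ self.dense_W[k].T
        dh = da * mask
        i, g, o, c = gates["i"], gates["g"], gates["o"], gates["c"]
        tc = np.tanh(c)
        do = dh * tc
        dc = dh * o * (1.0 - tc**2)
        di = dc * g
        dg = dc * i
        dz_i = di * i * (1.0 - i)
        dz_g = dg * (1.0 - g**2)
        dz_o = do * o * (1.0 - o)
        return [X.T @ dz_i, X.T @ dz_g, X.T @ dz_o, *grad_W, *grad_b]

    def train_batch(
        self,
        X: np.ndarray,
        t: np.ndarray,
        lr: float,
        momentum: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> float:
        """One SGD step on mean squared error; returns the batch loss."""
        out, cache = self.forward(X, train_rng=rng)
        resid = out - t
        loss = float(np.mean(resid**2))
        dout = 2.0 * resid / len(resid)
        grads = self._gradients(cache, dout)
        for p, v, grad in zip(self._params, self._velocity, grads):
            v *= momentum
            v -= lr * grad
            p += v
        return loss

    # -- weights snapshot (for early stopping) ------------------------------

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self._params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self._params, weights):
            p[...] = w
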