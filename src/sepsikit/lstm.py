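"""A small LSTM risk scorer implemented in NumPy.

Each stay's hourly feature rows form one sequence; the network is a
single-layer LSTM with a per-hour sigmoid readout, trained with masked
binary cross-entropy and Adam via hand-written backpropagation through time.
Sequences are end-padded to the longest stay in a minibatch, so padded steps
never contribute to the loss or to gradients of real steps. All arithmetic
is NumPy, single-threaded and seeded, so training is bit-reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ContractViolation


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class LSTMParams:
    """Weight container; gate order along the last axis is (i, f, g, o)."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        s_in = 1.0 / np.sqrt(n_in)
        s_h = 1.0 / np.sqrt(hidden)
        self.Wx = rng.uniform(-s_in, s_in, size=(n_in, 4 * hidden))
        self.Wh = rng.uniform(-s_h, s_h, size=(hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        self.b[hidden:2 * hidden] = 1.0  # forget-gate bias
        self.w_out = rng.uniform(-s_h, s_h, size=hidden)
        self.b_out = 0.0

    def as_list(self):
        return [self.Wx, self.Wh, self.b, self.w_out, np.atleast_1d(self.b_out)]


def _forward(params: LSTMParams, X: np.ndarray):
    """Run the LSTM over a batch. X is (B, T, D); returns logits and caches."""
    B, T, D = X.shape
    H = params.Wh.shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    logits = np.zeros((B, T))
    caches = []
    for t in range(T):
        x_t = X[:, t, :]
        pre = x_t @ params.Wx + h @ params.Wh + params.b
        i = _sigmoid(pre[:, :H])
        f = _sigmoid(pre[:, H:2 * H])
        g = np.tanh(pre[:, 2 * H:3 * H])
        o = _sigmoid(pre[:, 3 * H:])
        c_prev = c
        c = f * c_prev + i * g
        tanh_c = np.tanh(c)
        h_prev = h
        h = o * tanh_c
        logits[:, t] = h @ params.w_out + params.b_out
        caches.append((x_t, h_prev, c_prev, i, f, g, o, tanh_c, h))
    return logits, caches


def _backward(params: LSTMParams, X: np.ndarray, logits: np.ndarray,
              caches, y: np.ndarray, mask: np.ndarray):
    """Masked-BCE loss and gradients for every parameter."""
    B, T, D = X.shape
    H = params.Wh.shape[0]
    total = mask.sum()
    p = _sigmoid(logits)
    eps = 1e-12
    loss = -(mask * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))).sum() / total
    dlogits = (p - y) * mask / total

    dWx = np.zeros_like(params.Wx)
    dWh = np.zeros_like(params.Wh)
    db = np.zeros_like(params.b)
    dw_out = np.zeros_like(params.w_out)
    db_out = 0.0
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        x_t, h_prev, c_prev, i, f, g, o, tanh_c, h_t = caches[t]
        dl = dlogits[:, t]
        dw_out += h_t.T @ dl
        db_out += dl.sum()
        dh = dl[:, None] * params.w_out[None, :] + dh_next
        do = dh * tanh_c
        dc = dc_next + dh * o * (1.0 - tanh_c ** 2)
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dc_next = dc * f
        dpre = np.concatenate([
            di * i * (1 - i),
            df * f * (1 - f),
            dg * (1 - g ** 2),
            do * o * (1 - o),
        ], axis=1)
        dWx += x_t.T @ dpre
        dWh += h_prev.T @ dpre
        db += dpre.sum(axis=0)
        dh_next = dpre @ params.Wh.T
    return loss, [dWx, dWh, db, dw_out, np.atleast_1d(db_out)]


class LSTMScorer:
    """Recurrent per-hour sepsis risk scorer (NumPy LSTM, seeded)."""

    def __init__(self, hidden: int = 24, epochs: int = 8, lr: float = 5e-3,
                 batch_size: int = 64, seed: int = 0):
        self.hidden = hidden
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.seed = seed
        self.params: LSTMParams | None = None
        self._mean: np.ndarray | None = None
        self._scale: np.ndarray | None = None

    # -- sequence plumbing ------------------------------------------------
    def _standardize(self, X: pd.DataFrame, fit: bool) -> np.ndarray:
        vals = X.to_numpy(dtype=float)
        if fit:
            self._mean = vals.mean(axis=0)
            scale = vals.std(axis=0)
            scale[scale < 1e-8] = 1.0
            self._scale = scale
        return (vals - self._mean) / self._scale

    @staticmethod
    def _sequences(X: pd.DataFrame, vals: np.ndarray, y: np.ndarray | None):
        """Split standardized rows into per-stay sequences in hour order."""
        stay_ids = X.index.get_level_values(0).to_numpy()
        hours = X.index.get_level_values(1).to_numpy()
        order = np.lexsort((hours, stay_ids))
        seqs, targets, row_order = [], [], []
        start = 0
        sorted_sids = stay_ids[order]
        boundaries = np.flatnonzero(np.diff(sorted_sids)) + 1
        for chunk in np.split(order, boundaries):
            seqs.append(vals[chunk])
            targets.append(y[chunk] if y is not None else None)
            row_order.append(chunk)
        return seqs, targets, row_order

    @staticmethod
    def _pad(seqs: list[np.ndarray], targets: list[np.ndarray | None]):
        B = len(seqs)
        T = max(len(s) for s in seqs)
        D = seqs[0].shape[1]
        X = np.zeros((B, T, D))
        y = np.zeros((B, T))
        mask = np.zeros((B, T))
        for b, s in enumerate(seqs):
            X[b, :len(s)] = s
            mask[b, :len(s)] = 1.0
            if targets[b] is not None:
                y[b, :len(s)] = targets[b]
        return X, y, mask

    # -- training ---------------------------------------------------------
    def fit(self, X: pd.DataFrame, y: np.ndarray, groups: np.ndarray) -> "LSTMScorer":
        y = np.asarray(y, dtype=float)
        vals = self._standardize(X, fit=True)
        seqs, targets, _ = self._sequences(X, vals, y)
        rng = np.random.default_rng(self.seed)
        self.params = LSTMParams(vals.shape[1], self.hidden, rng)

        flat = self.params.as_list()
        m = [np.zeros_like(p) for p in flat]
        v = [np.zeros_like(p) for p in flat]
        step = 0
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        n = len(seqs)
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            for lo in range(0, n, self.batch_size):
                batch = order[lo:lo + self.batch_size]
                Xb, yb, maskb = self._pad([seqs[b] for b in batch],
                                          [targets[b] for b in batch])
                logits, caches = _forward(self.params, Xb)
                _loss, grads = _backward(self.params, Xb, logits, caches, yb, maskb)
                step += 1
                for p, gr, mi, vi in zip(flat, grads, m, v):
                    mi *= beta1
                    mi += (1 - beta1) * gr
                    vi *= beta2
                    vi += (1 - beta2) * gr * gr
                    mhat = mi / (1 - beta1 ** step)
                    vhat = vi / (1 - beta2 ** step)
                    p -= self.lr * mhat / (np.sqrt(vhat) + eps)
                self.params.b_out = float(flat[4][0])
        return self

    def score(self, X: pd.DataFrame) -> np.ndarray:
        if self.params is None:
            raise ContractViolation("score() called before fit()")
        vals = self._standardize(X, fit=False)
        seqs, _, row_order = self._sequences(X, vals, None)
        out = np.zeros(len(X))
        for lo in range(0, len(seqs), 256):
            chunk = seqs[lo:lo + 256]
            chunk_rows = row_order[lo:lo + 256]
            Xb, _, _ = self._pad(chunk, [None] * len(chunk))
            logits, _ = _forward(self.params, Xb)
            probs = _sigmoid(logits)
            for b, rows in enumerate(chunk_rows):
                out[rows] = probs[b, :len(rows)]
        return out
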