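"""Truncated path signatures of piecewise-linear paths.

The signature of a path :math:`X : [0, 1] \\to \\mathbb{R}^d` is the sequence
of iterated integrals

.. math::

    S^{(i_1, \\ldots, i_k)}(X)
      = \\int_{0 < t_1 < \\cdots < t_k < 1}
        dX^{i_1}_{t_1} \\cdots dX^{i_k}_{t_k},

a graded, reparameterization-invariant summary of the path's geometry that
is the canonical feature set for multivariate time series in this pipeline.
For a piecewise-linear path the signature is computed exactly: the signature
of a single linear segment with increment :math:`\\Delta` is the truncated
tensor exponential :math:`\\exp(\\Delta) = (1, \\Delta, \\Delta^{\\otimes 2}/2!,
\\ldots)`, and segments combine by Chen's identity (the truncated tensor
product). Coefficients are returned flattened, levels 1..depth concatenated
in lexicographic index order, with length :math:`d + d^2 + \\cdots + d^N`.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import ContractViolation


def signature_dim(channels: int, depth: int) -> int:
    """Length of the flattened signature: d + d^2 + ... + d^depth."""
    return sum(channels ** k for k in range(1, depth + 1))


def _segment_signature(delta: np.ndarray, depth: int) -> list[np.ndarray]:
    """Truncated tensor exponential of one linear segment's increment.

    Level k of exp(delta) is the k-fold outer power delta^{(x) k} / k!.
    """
    powers = [np.asarray(delta, dtype=float)]
    for _ in range(2, depth + 1):
        powers.append(np.multiply.outer(powers[-1], delta))
    return [p / math.factorial(k + 1) for k, p in enumerate(powers)]


def tensor_product(a: list[np.ndarray], b: list[np.ndarray], depth: int) -> list[np.ndarray]:
    """Truncated tensor-algebra product of two signatures (Chen's identity).

    ``a`` and ``b`` are lists of level tensors (level k has shape (d,)*k);
    the scalar level-0 coefficient 1 is implicit.
    """
    out: list[np.ndarray] = []
    for k in range(1, depth + 1):
        acc = None
        for j in range(0, k + 1):
            if j == 0:
                piece = b[k - 1]
            elif j == k:
                piece = a[k - 1]
            else:
                piece = np.multiply.outer(a[j - 1], b[k - j - 1])
            acc = piece if acc is None else acc + piece
        out.append(acc)
    return out


def signature_levels(path: np.ndarray, depth: int) -> list[np.ndarray]:
    """Signature of the piecewise-linear interpolation of ``path`` as level tensors."""
    path = np.asarray(path, dtype=float)
    if path.ndim == 1:
        path = path[:, None]
    if path.shape[0] < 2:
        raise ContractViolation("degenerate path: a signature needs at least 2 points")
    d = path.shape[1]
    deltas = np.diff(path, axis=0)
    sig = _segment_signature(deltas[0], depth)
    for delta in deltas[1:]:
        sig = tensor_product(sig, _segment_signature(delta, depth), depth)
    return sig


def signature_transform(path: np.ndarray, depth: int) -> np.ndarray:
    """Flattened truncated signature, levels 1..depth concatenated.

    Parameters
    ----------
    path : array (n_points, d) with n_points >= 2 (a 1-d array is treated as
        a single channel). When the path is time-augmented, time is by
        convention the first coordinate.
    depth : truncation order N >= 1.
    """
    if depth < 1:
        raise ContractViolation(f"signature depth must be >= 1, got {depth}")
    levels = signature_levels(path, depth)
    return np.concatenate([lv.ravel() for lv in levels])


def batch_signature_depth2(windows: np.ndarray) -> np.ndarray:
    """Depth-2 signatures of many equal-length paths at once.

    ``windows`` has shape (n_paths, n_points, d). Uses the exact
    piecewise-linear formulas: level 1 is the total increment; level 2 is
    S(i,j) = sum_k [ (x_{k-1,i} - x_{0,i}) dx_{k,j} + dx_{k,i} dx_{k,j} / 2 ].
    Matches ``signature_transform(path, 2)`` path-by-path.
    """
    w = np.asarray(windows, dtype=float)
    n, m, d = w.shape
    dx = np.diff(w, axis=1)                      # (n, m-1, d)
    lvl1 = dx.sum(axis=1)                        # (n, d)
    prefix = w[:, :-1, :] - w[:, :1, :]          # x_{k-1} - x_0
    lvl2 = np.einsum("nki,nkj->nij", prefix, dx) + 0.5 * np.einsum("nki,nkj->nij", dx, dx)
    return np.concatenate([lvl1, lvl2.reshape(n, d * d)], axis=1)
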