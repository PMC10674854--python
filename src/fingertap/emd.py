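"""Empirical Mode Decomposition by standard sifting.

Splits a signal into Intrinsic Mode Functions (IMFs), ordered highest
frequency first, plus a slow residual trend.  Sifting follows the classic
recipe: cubic-spline envelopes through the local maxima and minima (with
extrema mirrored across the signal ends to tame boundary effects) and
repeated subtraction of the envelope mean until the Rilling envelope-ratio
stopping criterion is met (see :func:`sift`).
Decomposition stops when the running residual has too few extrema to
support an envelope.  The returned residual is defined as
``input - sum(imfs)`` so the reconstruction identity holds to rounding error
on every input, including pathological ones.

The decomposition is fully deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

from .signal import EMDResult, TapSignal

__all__ = ["emd_decompose", "sift"]


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of interior local maxima and minima, plateau-safe.

    A plateau counts once (at its midpoint); signal endpoints are never
    extrema — boundary behaviour is handled by envelope mirroring instead.
    """
    d = np.sign(np.diff(x))
    nz = np.flatnonzero(d != 0)
    if nz.size == 0:  # constant signal
        return np.array([], dtype=int), np.array([], dtype=int)
    # forward-fill zero slopes so plateaus inherit the preceding direction
    filled = d.copy()
    last = d[nz[0]]
    for i in range(filled.size):
        if filled[i] == 0:
            filled[i] = last
        else:
            last = filled[i]
    turn = np.flatnonzero(filled[:-1] != filled[1:]) + 1
    maxima = turn[filled[turn] < 0]
    minima = turn[filled[turn] > 0]
    # centre each extremum inside its plateau, if any
    def _centre(idx: np.ndarray) -> np.ndarray:
        out = idx.copy()
        for k, i in enumerate(idx):
            j = i
            while j + 1 < x.size and x[j + 1] == x[i]:
                j += 1
            out[k] = (i + j) // 2
        return out

    return _centre(maxima), _centre(minima)


def _mirrored_envelope(idx: np.ndarray, vals: np.ndarray, n: int) -> np.ndarray:
    """Cubic-spline envelope through (idx, vals), extrema mirrored at both ends."""
    k = min(2, idx.size)
    left_idx = (2 * 0 - idx[:k][::-1]).astype(float)
    left_vals = vals[:k][::-1]
    right_idx = (2 * (n - 1) - idx[-k:][::-1]).astype(float)
    right_vals = vals[-k:][::-1]
    xs = np.concatenate([left_idx, idx.astype(float), right_idx])
    ys = np.concatenate([left_vals, vals, right_vals])
    xs, keep = np.unique(xs, return_index=True)
    ys = ys[keep]
    if xs.size < 2:
        return np.full(n, ys[0])
    if xs.size < 4:  # not enough knots for a cubic; fall back to linear
        return np.interp(np.arange(n), xs, ys)
    return CubicSpline(xs, ys)(np.arange(n))


def sift(
    x: np.ndarray,
    theta1: float = 0.05,
    theta2: float = 0.5,
    tolerance: float = 0.05,
    max_siftings: int = 100,
) -> np.ndarray | None:
    """Extract one IMF from ``x``; None if ``x`` has too few extrema.

    Stopping follows the Rilling envelope-ratio criterion: sifting ends when
    the envelope mean is small relative to the envelope amplitude
    a = (upper - lower)/2 — specifically |mean|/a < theta1 on all but a
    ``tolerance`` fraction of samples and |mean|/a < theta2 everywhere.
    Unlike the Cauchy SD criterion this is insensitive to a DC offset in the
    running residual, which would otherwise end sifting prematurely.
    """
    h = np.asarray(x, dtype=float).copy()
    n = h.size
    for _ in range(max_siftings):
        maxima, minima = _local_extrema(h)
        if maxima.size < 2 or minima.size < 2:
            return None
        # treat an end sample that pokes beyond the nearest extremum as a
        # knot itself, otherwise the envelope undershoots a running trend
        if h[0] > h[maxima[0]]:
            maxima = np.concatenate(([0], maxima))
        if h[-1] > h[maxima[-1]]:
            maxima = np.concatenate((maxima, [n - 1]))
        if h[0] < h[minima[0]]:
            minima = np.concatenate(([0], minima))
        if h[-1] < h[minima[-1]]:
            minima = np.concatenate((minima, [n - 1]))
        upper = _mirrored_envelope(maxima, h[maxima], n)
        lower = _mirrored_envelope(minima, h[minima], n)
        mean = 0.5 * (upper + lower)
        amp = np.maximum(0.5 * (upper - lower), 1e-300)
        ratio = np.abs(mean) / amp
        h = h - mean
        if np.mean(ratio > theta1) < tolerance and ratio.max() < theta2:
            # also require the IMF property: extrema and zero-crossing
            # counts differ by at most one, so no oscillation rides wholly
            # above or below zero (that content belongs in this mode, not
            # the next)
            mx, mn = _local_extrema(h)
            n_zc = int(np.sum(np.diff(np.signbit(h)) != 0))
            if abs((mx.size + mn.size) - n_zc) <= 1:
                break
    return h


def emd_decompose(
    signal: TapSignal | np.ndarray,
    max_imfs: int = 12,
    max_siftings: int = 100,
) -> EMDResult:
    """Decompose a signal into IMFs + residual.

    A constant or monotone signal yields zero IMFs and a residual equal to
    the input.  ``sum(imfs) + residual`` equals the input to rounding error.

    Parameters
    ----------
    signal
        TapSignal or plain 1-D array, length >= 4, finite values.
    max_imfs
        Safety cap on the number of extracted modes.
    """
    x = signal.values if isinstance(signal, TapSignal) else np.asarray(signal, float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("EMD requires a 1-D signal of length >= 4")
    if not np.isfinite(x).all():
        raise ValueError("EMD requires finite values (interpolate dropouts first)")

    imfs: list[np.ndarray] = []
    residual = x.copy()
    for _ in range(max_imfs):
        imf = sift(residual, max_siftings=max_siftings)
        if imf is None:
            break
        imfs.append(imf)
        residual = residual - imf
    # define residual by exact subtraction so reconstruction is an identity
    residual = x - np.sum(imfs, axis=0) if imfs else x.copy()
    return EMDResult(imfs=imfs, residual=residual)
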