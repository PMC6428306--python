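"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain double loops / direct definitions,
deliberately avoiding the FFT-based code paths of the package.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve


def bf_bspline(m: int, num_samples: int, dx: float = 2e-5) -> np.ndarray:
    """Order-m B-spline by m-fold self-convolution of a box window.

    The box is sampled at spacing ``dx`` (half-weight endpoints, i.e.
    trapezoid-rule convolution, error O(dx^2)) and convolved with itself
    m-1 times, then interpolated onto the ``num_samples`` output grid
    and peak-normalized.
    """
    n_box = int(round(1.0 / dx)) + 1
    box = np.ones(n_box)
    box[0] = box[-1] = 0.5
    cur = box.copy()
    for _ in range(m - 1):
        cur = fftconvolve(cur, box) * dx
    x_fine = np.arange(cur.size) * dx  # spans [0, m]
    x_out = np.linspace(0.0, float(m), num_samples)
    out = np.interp(x_out, x_fine, cur)
    return out / out.max()


def bf_windowed_sum(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """y[b] = sum_i taps[i] * x[b+i-c], zero-padded, c = (n-1)//2."""
    n = len(taps)
    c = (n - 1) // 2
    N = len(x)
    out = np.zeros(N, dtype=complex if np.iscomplexobj(taps) else float)
    for b in range(N):
        acc = 0.0
        for i in range(n):
            idx = b + i - c
            if 0 <= idx < N:
                acc += taps[i] * x[idx]
        out[b] = acc
    return out


def bf_domain(values: np.ndarray, bank) -> np.ndarray:
    rows = [
        bf_windowed_sum(values, bank.taps[j]) / bank.windows[j].sum()
        for j in range(len(bank.scales))
    ]
    return np.vstack(rows)


def bf_range(values: np.ndarray, bank, tau0: int, mode: str) -> np.ndarray:
    N = len(values)
    d = np.zeros(N)
    for t in range(tau0, N):
        d[t] = abs(values[t] - values[t - tau0])
    rows = [
        bf_windowed_sum(d, bank.windows[j]).real / bank.windows[j].sum()
        for j in range(len(bank.scales))
    ]
    R = np.vstack(rows)
    if mode == "inverted":
        R = np.array([row.max() - row for row in R])
    return R


def bf_multiscale_products(U: np.ndarray) -> np.ndarray:
    J, N = U.shape
    MP = np.zeros((J - 1, N))
    for j in range(J - 1):
        for b in range(N):
            MP[j, b] = abs(U[j, b]) * abs(U[j + 1, b])
    return MP


def bf_spectrum(MP: np.ndarray) -> np.ndarray:
    K, N = MP.shape
    S = np.zeros(N)
    for b in range(N):
        for j in range(K):
            S[b] += MP[j, b] ** 2
    return S


def pair_count_auc(scores: np.ndarray, mask: np.ndarray) -> float:
    """AUC as the Mann-Whitney pair-ordering probability (ties count 1/2)."""
    pos = scores[mask]
    neg = scores[~mask]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
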