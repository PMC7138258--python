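"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately avoid the library's vectorized implementations: binning
is done by explicit comparisons against edge arrays, histograms by double
loops, quantiles by sort-and-interpolate.
"""

from __future__ import annotations

import numpy as np


def oracle_bin(value, edges):
    """Comparison-based bin lookup on log10 edges.

    Bins are (edge[i], edge[i+1]]; values above the top edge overflow into
    the highest bin; values at or below the bottom edge are excluded
    (returns None).
    """
    if value <= 0:
        return None
    lv = np.log10(value)
    if lv <= edges[0]:
        return None
    if lv > edges[-1]:
        return len(edges) - 2
    for i in range(len(edges) - 1):
        if edges[i] < lv <= edges[i + 1]:
            return i
    raise AssertionError("unreachable")


def oracle_ci(signal, fcm, cfg):
    """Naive double-loop context-image construction."""
    s_edges = np.linspace(*cfg.signal_log_range(), cfg.n_bins + 1)
    f_edges = np.linspace(*cfg.fcm_log_range(), cfg.n_bins + 1)
    counts = np.zeros((cfg.n_bins, cfg.n_bins), dtype=np.int64)
    for i in range(signal.shape[0]):
        for j in range(signal.shape[1]):
            if not fcm[i, j] > cfg.fcm_epsilon:
                continue
            sb = oracle_bin(signal[i, j], s_edges)
            fb = oracle_bin(fcm[i, j], f_edges)
            if sb is None or fb is None:
                continue
            counts[sb, fb] += 1
    return counts


def oracle_quantile(values, q):
    """Sort-and-interpolate quantile (linear interpolation convention)."""
    v = sorted(values)
    pos = q * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


def oracle_nnls_grid(b, a, lo=0.0, hi=2.0, n=81, levels=3):
    """Two-variable non-negative least squares by refined grid search."""
    best = None
    step = (hi - lo) / (n - 1)
    g0 = np.linspace(lo, hi, n)
    g1 = np.linspace(lo, hi, n)
    for _ in range(levels):
        xx, yy = np.meshgrid(g0, g1, indexing="ij")
        resid = ((a[:, 0][:, None, None] * xx
                  + a[:, 1][:, None, None] * yy
                  - b[:, None, None]) ** 2).sum(axis=0)
        i, j = np.unravel_index(np.argmin(resid), resid.shape)
        best = np.array([xx[i, j], yy[i, j]])
        step = (g0[1] - g0[0]) * 2
        g0 = np.linspace(max(0, best[0] - step), best[0] + step, n)
        g1 = np.linspace(max(0, best[1] - step), best[1] + step, n)
    return best
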