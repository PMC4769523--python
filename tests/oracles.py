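"""Independent brute-force oracles used across the test suite.

These deliberately avoid the implementation's code paths: plain polyfit /
dense-grid / pairwise-count formulations of the same quantities.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_segmented(x, y, w):
    """Exhaustive two-segment weighted least squares.

    Tries every split with >= 2 points per side, fits each side with
    ``np.polyfit`` (weights enter as sqrt of the bin counts), and returns
    (sse, bk, a0, b0, a1, b1) of the global minimum (ties -> smaller bk).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    best = None
    for s in range(2, len(x) - 1):
        a0, b0 = np.polyfit(x[:s], y[:s], 1, w=np.sqrt(w[:s]))
        a1, b1 = np.polyfit(x[s:], y[s:], 1, w=np.sqrt(w[s:]))
        sse = float((w[:s] * (y[:s] - a0 * x[:s] - b0) ** 2).sum()
                    + (w[s:] * (y[s:] - a1 * x[s:] - b1) ** 2).sum())
        bk = 0.5 * (x[s - 1] + x[s])
        if best is None or sse < best[0] - 1e-9 * max(1.0, best[0]):
            best = (sse, bk, a0, b0, a1, b1)
    return best


def grid_mle_llr(minor_eps, major_eps, n_points: int = 100_001):
    """Dense-grid argmax of the site likelihood over f in [0, 0.5] and the
    corresponding log10 likelihood ratio vs f = 0."""
    f = np.linspace(0.0, 0.5, n_points)[:, None]
    ll = np.zeros(n_points)
    me = np.asarray(minor_eps, float)
    Me = np.asarray(major_eps, float)
    if me.size:
        ll += np.log((1 - f) * me + f * (1 - me)).sum(axis=1)
    if Me.size:
        ll += np.log((1 - f) * (1 - Me) + f * Me).sum(axis=1)
    i = int(np.argmax(ll))
    return float(f[i, 0]), max(float((ll[i] - ll[0]) / math.log(10.0)), 0.0)


def auc_concordance(scores, labels):
    """AUC as the concordant-pair fraction with half credit for ties."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    pos = s[y][:, None]
    neg = s[~y][None, :]
    gt = (pos > neg).sum()
    eq = (pos == neg).sum()
    return (gt + 0.5 * eq) / (pos.size * neg.shape[1])


def direct_product_likelihood(f, minor_eps, major_eps):
    """L(f) as a plain python product (no log space)."""
    out = 1.0
    for e in minor_eps:
        out *= (1 - f) * e + f * (1 - e)
    for e in major_eps:
        out *= (1 - f) * (1 - e) + f * e
    return out
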