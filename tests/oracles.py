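"""Independent brute-force reference implementations used only by tests.

These deliberately mirror the defining formulas literally (plain Python
loops, textbook algebra) and share no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def ncc_literal(s, t) -> np.ndarray:
    """Literal per-lag evaluation of the normalized cross-correlation."""
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    L = len(t)
    mu_t = sum(t) / L
    out = []
    for k in range(len(s) - L + 1):
        w = s[k : k + L]
        mu_w = sum(w) / L
        num = sum((w[i] - mu_w) * (t[i] - mu_t) for i in range(L))
        den = math.sqrt(
            sum((w[i] - mu_w) ** 2 for i in range(L))
            * sum((t[i] - mu_t) ** 2 for i in range(L))
        )
        out.append(0.0 if den == 0.0 else num / den)
    return np.asarray(out)


def prominence_literal(values, idx: int) -> float:
    """Topographic prominence of the local maximum at ``idx`` by direct walk."""
    v = np.asarray(values, dtype=float)
    peak = v[idx]
    bases = []
    for step in (-1, 1):
        i = idx
        lowest = peak
        base = None
        while 0 <= i + step < len(v):
            i += step
            if v[i] > peak:
                base = lowest
                break
            lowest = min(lowest, v[i])
        if base is None:
            base = lowest
        bases.append(base)
    return peak - max(bases)


def local_maxima(values) -> list[int]:
    v = np.asarray(values, dtype=float)
    return [i for i in range(1, len(v) - 1) if v[i] > v[i - 1] and v[i] > v[i + 1]]


def ols_literal(x, y) -> tuple[float, float, float]:
    """Textbook least squares of y on x plus squared Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxx = sum((xi - mx) ** 2 for xi in x)
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    syy = sum((yi - my) ** 2 for yi in y)
    slope = sxy / sxx
    intercept = my - slope * mx
    r2 = sxy**2 / (sxx * syy)
    return slope, intercept, r2


def bland_altman_literal(ecg, scg) -> tuple[float, float]:
    """Textbook bias and 1.96 x sample-SD limits-of-agreement half-width."""
    d = [s - e for e, s in zip(ecg, scg)]
    n = len(d)
    bias = sum(d) / n
    var = sum((di - bias) ** 2 for di in d) / (n - 1)
    return bias, 1.96 * math.sqrt(var)
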