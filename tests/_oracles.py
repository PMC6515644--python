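"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (per-pixel loops, complete enumeration,
closed forms) kept separate from the package code paths they check.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def bernsen_bruteforce(arr: np.ndarray, radius: int, contrast_min: float,
                       low_contrast_foreground: bool = False) -> np.ndarray:
    """Per-pixel Bernsen: scan the full circular neighbourhood for every pixel."""
    arr = np.asarray(arr, dtype=float)
    h, w = arr.shape
    out = np.zeros((h, w), dtype=bool)
    offs = [(dr, dc) for dr in range(-radius, radius + 1)
            for dc in range(-radius, radius + 1)
            if dr * dr + dc * dc <= radius * radius]
    for r in range(h):
        for c in range(w):
            vals = [arr[r + dr, c + dc] for dr, dc in offs
                    if 0 <= r + dr < h and 0 <= c + dc < w]
            lo, hi = min(vals), max(vals)
            if hi - lo < contrast_min:
                out[r, c] = low_contrast_foreground
            else:
                out[r, c] = arr[r, c] >= (lo + hi) / 2.0
    return out


def count_and(*masks: np.ndarray) -> int:
    """Double-loop pixel count of the intersection of boolean masks."""
    h, w = masks[0].shape
    total = 0
    for r in range(h):
        for c in range(w):
            if all(m[r, c] for m in masks):
                total += 1
    return total


def point_in_polygon(x: float, y: float, vertices) -> bool:
    """Even-odd ray casting; boundary points count as inside."""
    n = len(vertices)
    inside = False
    for i in range(n):
        x0, y0 = vertices[i]
        x1, y1 = vertices[(i + 1) % n]
        # boundary check: point on segment
        cross = (x1 - x0) * (y - y0) - (y1 - y0) * (x - x0)
        if abs(cross) < 1e-12:
            if (min(x0, x1) - 1e-12 <= x <= max(x0, x1) + 1e-12
                    and min(y0, y1) - 1e-12 <= y <= max(y0, y1) + 1e-12):
                return True
        if (y0 > y) != (y1 > y):
            xi = x0 + (y - y0) * (x1 - x0) / (y1 - y0)
            if x < xi:
                inside = not inside
    return inside


def otsu_exhaustive(values: np.ndarray) -> int:
    """Between-class-variance scan over all 256 integer cutoffs."""
    vals = np.asarray(values).astype(int).ravel()
    hist = np.bincount(vals, minlength=256).astype(float)
    p = hist / hist.sum()
    best_t, best_var = 0, -1.0
    levels = np.arange(256)
    for t in range(1, 256):
        w0 = p[:t].sum()
        w1 = 1 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (levels[:t] * p[:t]).sum() / w0
        mu1 = (levels[t:] * p[t:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def anova_type3_oracle(y, a, b):
    """Type III 2x2 ANOVA via explicit full-vs-reduced normal-equation fits,
    checked independently of the package implementation through statsmodels."""
    import pandas as pd
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame({"y": y, "a": a, "b": b})
    model = smf.ols("y ~ C(a, Sum) * C(b, Sum)", data=df).fit()
    tab = anova_lm(model, typ=3)
    return {
        "factorA": (tab.loc["C(a, Sum)", "F"], tab.loc["C(a, Sum)", "PR(>F)"]),
        "factorB": (tab.loc["C(b, Sum)", "F"], tab.loc["C(b, Sum)", "PR(>F)"]),
        "interaction": (tab.loc["C(a, Sum):C(b, Sum)", "F"],
                        tab.loc["C(a, Sum):C(b, Sum)", "PR(>F)"]),
    }


def mann_whitney_enumeration(x, y):
    """Exact two-sided Mann-Whitney p by enumerating every group labeling."""
    pooled = list(x) + list(y)
    nx = len(x)
    n = len(pooled)

    def u_stat(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n) if i not in idx]
        u = 0.0
        for xi in xs:
            for yj in ys:
                if xi > yj:
                    u += 1.0
                elif xi == yj:
                    u += 0.5
        return u

    obs = u_stat(tuple(range(nx)))
    mu = nx * (n - nx) / 2.0
    dev = abs(obs - mu)
    count = sum(1 for idx in itertools.combinations(range(n), nx)
                if abs(u_stat(idx) - mu) >= dev - 1e-12)
    return obs, count / comb(n, nx)


def student_t_oracle(x, y):
    """Closed-form pooled-variance t test evaluated directly."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp2 = (((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
           / (nx + ny - 2))
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    from scipy.stats import t as tdist
    p = 2 * tdist.sf(abs(t), nx + ny - 2)
    return t, nx + ny - 2, p
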