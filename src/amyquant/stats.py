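"""Factorial statistics on per-animal metric tables.

The omnibus analysis is a two-factor ANOVA with interaction (amyloid-model
genotype x apoA-I genotype), computed with Type III sums of squares under
sum-to-zero contrasts so that unbalanced group sizes are handled the way
mainstream commercial packages do. Significant omnibus effects gate Sidak-
adjusted pairwise comparisons on the pooled residual variance. Unpaired
t tests (Student or Welch) and an exact Mann-Whitney U test cover the
two-group comparisons used for amyloid endpoints.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Dict, Hashable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05

#: Default Sidak family: simple effects of each factor within the other
#: (KO vs HEM within each amyloid-genotype level, transgenic vs WT within
#: each apoA-I level), m = 4.
DEFAULT_COMPARISONS: List[Tuple[Tuple[str, str], Tuple[str, str]]] = [
    (("WT", "KO"), ("WT", "HEM")),
    (("APPPS1", "KO"), ("APPPS1", "HEM")),
    (("APPPS1", "HEM"), ("WT", "HEM")),
    (("APPPS1", "KO"), ("WT", "KO")),
]


@dataclass
class AnovaTable:
    """Two-way ANOVA decomposition (Type III, sum-to-zero coding)."""

    factor_names: Tuple[str, str]
    effects: Dict[str, Dict[str, float]]  # effect -> {ss, df, ms, F, p}
    ms_residual: float
    df_residual: int
    cell_means: Dict[Tuple[Hashable, Hashable], float]
    cell_ns: Dict[Tuple[Hashable, Hashable], int]
    zero_residual: bool = False

    def p(self, effect: str) -> float:
        return self.effects[effect]["p"]

    @property
    def any_significant(self) -> bool:
        ps = [self.effects[e]["p"] for e in ("factorA", "factorB", "interaction")]
        return any(np.isfinite(p) and p < ALPHA for p in ps)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        names = {"factorA": self.factor_names[0],
                 "factorB": self.factor_names[1],
                 "interaction": ":".join(self.factor_names),
                 "residual": "residual"}
        for eff in ("factorA", "factorB", "interaction", "residual"):
            d = self.effects[eff]
            rows.append({"effect": names[eff], "sum_sq": d["ss"],
                         "df": d["df"], "mean_sq": d["ms"],
                         "F": d.get("F", np.nan), "p": d.get("p", np.nan)})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        return self.to_frame().to_string(index=False,
                                         float_format=lambda v: f"{v:.6g}")


@dataclass
class ComparisonResult:
    """One Sidak-adjusted pairwise comparison."""

    pair: Tuple[Hashable, Hashable]
    mean_diff: float
    t_stat: float
    df: int
    p_raw: float
    p_adj: float
    m: int


def _sse(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def two_way_anova(values: Sequence[float], factor_a: Sequence,
                  factor_b: Sequence,
                  factor_names: Tuple[str, str] = ("app_genotype",
                                                   "apoa1_genotype")
                  ) -> AnovaTable:
    """Type III two-way ANOVA with interaction for a 2x2 design.

    Each effect's sum of squares is the increase in residual sum of squares
    when that effect's sum-to-zero column is dropped from the full model
    (full-vs-reduced least-squares comparison), which makes the decomposition
    invariant to unbalanced cell sizes. F = MS_effect / MS_residual with
    p from the F distribution. A zero residual variance is flagged and the
    p-values reported as NaN.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("values and factors must be equal length")
    la, lb = np.unique(a), np.unique(b)
    if len(la) != 2 or len(lb) != 2:
        raise ValueError("two_way_anova requires exactly 2 levels per factor")
    cells = {(ai, bi): y[(a == ai) & (b == bi)] for ai in la for bi in lb}
    for cell, vals in cells.items():
        if len(vals) == 0:
            raise ValueError(f"empty cell {cell}")
    n = len(y)
    if n - 4 < 1:
        raise ValueError("residual df < 1")

    # sum-to-zero (effect) coding
    ca = np.where(a == la[0], 1.0, -1.0)
    cb = np.where(b == lb[0], 1.0, -1.0)
    intercept = np.ones(n)
    cols = {"factorA": ca, "factorB": cb, "interaction": ca * cb}
    X_full = np.column_stack([intercept, ca, cb, ca * cb])
    sse_full = _sse(y, X_full)
    df_res = n - 4
    ms_res = sse_full / df_res
    zero_resid = ms_res <= max(1e-30, 1e-14 * float(y @ y) / max(n, 1))

    effects: Dict[str, Dict[str, float]] = {}
    for eff in ("factorA", "factorB", "interaction"):
        keep = [intercept] + [v for k, v in cols.items() if k != eff]
        ss = _sse(y, np.column_stack(keep)) - sse_full
        ss = max(ss, 0.0)
        if zero_resid:
            F, p = np.nan, np.nan
        else:
            F = (ss / 1.0) / ms_res
            p = float(sps.f.sf(F, 1, df_res))
        effects[eff] = {"ss": ss, "df": 1, "ms": ss, "F": F, "p": p}
    effects["residual"] = {"ss": sse_full, "df": df_res, "ms": ms_res,
                           "F": np.nan, "p": np.nan}
    return AnovaTable(factor_names, effects, ms_res, df_res,
                      {k: float(v.mean()) for k, v in cells.items()},
                      {k: int(len(v)) for k, v in cells.items()},
                      zero_residual=zero_resid)


def sidak_pairwise(values: Sequence[float], groups: Sequence[Hashable],
                   comparisons: Sequence[Tuple[Hashable, Hashable]],
                   anova: AnovaTable) -> List[ComparisonResult]:
    """Sidak-adjusted pairwise comparisons on the pooled residual variance.

    t = (mean_i - mean_j) / sqrt(MS_res (1/n_i + 1/n_j)), df = residual df,
    p_adj = 1 - (1 - p_raw)^m with m the family size (always reported).
    """
    y = np.asarray(values, dtype=float)
    g = list(groups)
    m = len(comparisons)
    out: List[ComparisonResult] = []
    for gi, gj in comparisons:
        xi = y[[k == gi for k in g]]
        xj = y[[k == gj for k in g]]
        if len(xi) == 0 or len(xj) == 0:
            raise ValueError(f"comparison references unknown group ({gi}, {gj})")
        diff = float(xi.mean() - xj.mean())
        se = float(np.sqrt(anova.ms_residual * (1 / len(xi) + 1 / len(xj))))
        if se == 0:
            t, p_raw = (0.0, 1.0) if diff == 0 else (np.inf, 0.0)
        else:
            t = diff / se
            p_raw = float(2 * sps.t.sf(abs(t), anova.df_residual))
        p_adj = p_raw if m == 1 else float(
            np.clip(1.0 - (1.0 - p_raw) ** m, p_raw, 1.0))
        out.append(ComparisonResult((gi, gj), diff, t, anova.df_residual,
                                    p_raw, p_adj, m))
    return out


def unpaired_t(x: Sequence[float], y: Sequence[float],
               welch: bool = False) -> Tuple[float, float, float]:
    """Two-sided unpaired t test: Student (pooled variance) or Welch.

    Returns (t, df, p); a zero pooled variance yields NaN statistics.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need n >= 2 per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() != y.mean():
        return np.nan, np.nan, np.nan  # zero variance, nonzero difference
    res = sps.ttest_ind(x, y, equal_var=not welch)
    df = float(res.df)
    return float(res.statistic), df, float(res.pvalue)


def mann_whitney(x: Sequence[float], y: Sequence[float],
                 exact_max_n: int = 16) -> Tuple[float, float]:
    """Mann-Whitney U with exact two-sided p for small samples.

    U counts pairs with x > y plus half the tied pairs. When
    n_x + n_y <= ``exact_max_n`` the two-sided p is computed by complete
    enumeration of all C(n, n_x) group labelings of the pooled data (valid
    with ties); otherwise the normal approximation with tie and continuity
    corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 1 or ny < 1:
        raise ValueError("need n >= 1 per group")
    pooled = np.concatenate([x, y])
    n = nx + ny
    greater = (pooled[:, None] > pooled[None, :]).astype(float)
    greater += 0.5 * (pooled[:, None] == pooled[None, :])
    np.fill_diagonal(greater, 0.0)

    def u_of(idx: Tuple[int, ...]) -> float:
        sel = np.zeros(n, dtype=bool)
        sel[list(idx)] = True
        return float(greater[np.ix_(sel, ~sel)].sum())

    U = u_of(tuple(range(nx)))
    mu = nx * ny / 2.0
    if n <= exact_max_n:
        dev = abs(U - mu)
        count = sum(1 for idx in itertools.combinations(range(n), nx)
                    if abs(u_of(idx) - mu) >= dev - 1e-12)
        p = count / comb(n, nx)
        return U, float(min(p, 1.0))
    # normal approximation with tie correction and continuity correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum()) / (n * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return U, 1.0
    z = (abs(U - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    p = float(min(2 * sps.norm.sf(z), 1.0))
    return U, p


# ---------------------------------------------------------------------------
# metric-table driver

def analyze_metric_table(table: pd.DataFrame,
                         comparisons: Optional[Sequence] = None,
                         posthoc_gate: bool = True
                         ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run the omnibus ANOVA (+ gated Sidak post hoc) per metric/region.

    ``table`` is tidy per-animal data with columns animal_id, app_genotype,
    apoa1_genotype, region, metric, value. Post-hoc comparisons are emitted
    only when an omnibus effect is significant at alpha = 0.05 unless
    ``posthoc_gate`` is disabled. Returns (anova_frame, comparisons_frame).
    """
    comparisons = list(comparisons) if comparisons is not None \
        else DEFAULT_COMPARISONS
    anova_rows, comp_rows = [], []
    for (metric, region), sub in table.groupby(["metric", "region"],
                                               sort=True):
        sub = sub.dropna(subset=["value"])
        counts = sub.groupby(["app_genotype", "apoa1_genotype"]).size()
        if len(counts) < 4 or counts.min() < 1 or len(sub) - 4 < 1:
            continue
        tab = two_way_anova(sub["value"], sub["app_genotype"],
                            sub["apoa1_genotype"])
        for _, row in tab.to_frame().iterrows():
            anova_rows.append({"metric": metric, "region": region,
                               **row.to_dict()})
        if posthoc_gate and not tab.any_significant:
            continue
        groups = list(zip(sub["app_genotype"], sub["apoa1_genotype"]))
        for res in sidak_pairwise(sub["value"], groups, comparisons, tab):
            comp_rows.append({
                "metric": metric, "region": region,
                "group_i": "/".join(res.pair[0]),
                "group_j": "/".join(res.pair[1]),
                "mean_diff": res.mean_diff, "t": res.t_stat, "df": res.df,
                "p_raw": res.p_raw, "p_adj": res.p_adj, "m": res.m})
    anova_cols = ["metric", "region", "effect", "sum_sq", "df", "mean_sq",
                  "F", "p"]
    comp_cols = ["metric", "region", "group_i", "group_j", "mean_diff", "t",
                 "df", "p_raw", "p_adj", "m"]
    return (pd.DataFrame(anova_rows, columns=anova_cols),
            pd.DataFrame(comp_rows, columns=comp_cols))
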