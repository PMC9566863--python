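"""First-principles implementations of the study's statistical procedures.

Every test used downstream lives here: Welch's unequal-variance t test,
the two-sided Wilcoxon rank-sum test (exact by enumeration for small
samples, normal approximation with tie and continuity corrections
otherwise), two-way ANOVA with Type III sums of squares under sum-to-zero
coding (the convention of the GUI package the assays were analysed with),
the Šidák multiple-comparison adjustment, and the Mantel–Cox (log-rank)
test for survival curves.

Tail probabilities are computed through the regularized incomplete beta
and gamma functions rather than through a stats library's test objects,
so each procedure here can be validated against independent oracles
(enumeration, design-matrix projections, risk-set tabulation).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "StatResult",
    "welch_t",
    "wilcoxon_rank_sum",
    "two_way_anova",
    "TwoWayAnovaResult",
    "pairwise_contrasts",
    "sidak_adjust",
    "mantel_cox",
]


@dataclass
class StatResult:
    """Outcome of a single hypothesis test.

    ``df`` is fractional for Welch's t (Welch–Satterthwaite) and may be a
    pair ``(df_num, df_den)`` for F statistics. ``p_adjusted`` is filled
    only when a multiplicity correction was applied; it is never below the
    raw p-value.
    """

    test: str
    statistic: float
    df: float | tuple[float, float] | None
    p_value: float
    p_adjusted: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


# ---------------------------------------------------------------------------
# tail probabilities via regularized incomplete beta / gamma
# ---------------------------------------------------------------------------

def _t_sf(t: float, df: float) -> float:
    """P(T >= t) for Student's t with ``df`` degrees of freedom."""
    if df <= 0:
        raise ValueError("df must be positive")
    x = df / (df + t * t)
    p = 0.5 * special.betainc(df / 2.0, 0.5, x)
    return p if t >= 0 else 1.0 - p


def _f_sf(f: float, df1: float, df2: float) -> float:
    """P(F >= f) for the F distribution."""
    if f <= 0:
        return 1.0
    return special.betainc(df2 / 2.0, df1 / 2.0, df2 / (df2 + df1 * f))


def _chi2_sf(x: float, df: float) -> float:
    """P(X >= x) for the chi-square distribution."""
    if x <= 0:
        return 1.0
    return float(special.gammaincc(df / 2.0, x / 2.0))


def _norm_sf(z: float) -> float:
    return 0.5 * math.erfc(z / math.sqrt(2.0))


# ---------------------------------------------------------------------------
# Welch's t
# ---------------------------------------------------------------------------

def welch_t(x, y) -> StatResult:
    """Unpaired two-sample t test with Welch's correction (two-sided).

    t = (x̄ − ȳ) / sqrt(sx²/nx + sy²/ny); the degrees of freedom follow
    Welch–Satterthwaite and are generally fractional. Both samples must
    have at least two observations. If both groups have zero variance the
    test degenerates: equal means give t = 0, p = 1; unequal means give
    p = 0 flagged ``degenerate`` in ``extra``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("welch_t requires at least 2 observations per group")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    summary = {
        "n_x": nx, "n_y": ny,
        "mean_x": mx, "mean_y": my,
        "sd_x": math.sqrt(vx), "sd_y": math.sqrt(vy),
    }
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        if mx == my:
            return StatResult("welch_t", 0.0, float(nx + ny - 2), 1.0, extra=summary)
        summary["degenerate"] = True
        stat = math.inf if mx > my else -math.inf
        return StatResult("welch_t", stat, float(nx + ny - 2), 0.0, extra=summary)
    t = (mx - my) / math.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = min(1.0, 2.0 * _t_sf(abs(t), df))
    return StatResult("welch_t", t, df, p, extra=summary)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(x, y, exact_max_n: int = 8) -> StatResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Ties receive midranks. When both samples have at most ``exact_max_n``
    observations and there are no ties, the p-value is exact: the null
    distribution of the rank sum is enumerated over all C(nx+ny, nx)
    assignments of ranks to the first sample. Otherwise a normal
    approximation with tie correction and a 0.5 continuity correction is
    used. If every value in both groups is identical, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 1 or ny < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return StatResult("wilcoxon_rank_sum", 0.0, None, 1.0,
                          extra={"n_x": nx, "n_y": ny, "method": "degenerate"})
    ranks = _midranks(pooled)
    w = float(ranks[:nx].sum())  # rank sum of x
    has_ties = np.unique(pooled).size < pooled.size
    if nx <= exact_max_n and ny <= exact_max_n and not has_ties:
        p, method = _exact_rank_sum_p(w, nx, ny), "exact"
    else:
        p, method = _approx_rank_sum_p(w, nx, ny, pooled), "normal_approx"
    u = w - nx * (nx + 1) / 2.0
    return StatResult(
        "wilcoxon_rank_sum", w, None, p,
        extra={"n_x": nx, "n_y": ny, "U": u, "method": method},
    )


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(values.size, dtype=float)
    sv = values[order]
    i = 0
    while i < sv.size:
        j = i
        while j + 1 < sv.size and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _exact_rank_sum_p(w: float, nx: int, ny: int) -> float:
    n = nx + ny
    total = math.comb(n, nx)
    lo = hi = 0
    for combo in itertools.combinations(range(1, n + 1), nx):
        s = sum(combo)
        if s <= w:
            lo += 1
        if s >= w:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def _approx_rank_sum_p(w: float, nx: int, ny: int, pooled: np.ndarray) -> float:
    n = nx + ny
    mean = nx * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (n * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    d = abs(w - mean) - 0.5  # continuity correction
    z = max(d, 0.0) / math.sqrt(var)
    return min(1.0, 2.0 * _norm_sf(z))


# ---------------------------------------------------------------------------
# two-way ANOVA (Type III / Type II, sum-to-zero coding)
# ---------------------------------------------------------------------------

@dataclass
class TwoWayAnovaResult:
    """Full two-way ANOVA decomposition for factors A, B, and A×B.

    ``effects`` maps effect name (factor_a, factor_b, "interaction") to a
    StatResult carrying F, (df_num, df_den) and p. ``mse``/``df_error``
    support pooled-error post-hoc contrasts; ``cell_stats`` holds per-cell
    n/mean/sd keyed by (level_a, level_b).
    """

    factor_a: str
    factor_b: str
    effects: dict
    ss: dict
    ss_total: float
    ss_error: float
    df_error: int
    mse: float
    cell_stats: dict
    ss_type: str


def _sum_to_zero_codes(levels: np.ndarray, values: np.ndarray) -> np.ndarray:
    """(n, k-1) sum-to-zero contrast columns for a categorical factor."""
    k = levels.size
    cols = np.zeros((values.size, k - 1))
    for j in range(k - 1):
        cols[values == levels[j], j] = 1.0
        cols[values == levels[k - 1], j] = -1.0
    return cols


def _sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def two_way_anova(
    data: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
    ss_type: str = "III",
) -> TwoWayAnovaResult:
    """Two-way fixed-effects ANOVA with interaction.

    Requires every cell of the A×B cross to be present with at least two
    replicates. Sums of squares are Type III by default (each effect
    tested by dropping its sum-to-zero contrast columns from the full
    model), matching the convention of the GUI stats package the assays
    were originally analysed with; Type II is available. On balanced
    designs both reduce to the classical decomposition and
    SS_A + SS_B + SS_AB + SS_error = SS_total.
    """
    if ss_type not in {"II", "III"}:
        raise ValueError("ss_type must be 'II' or 'III'")
    y = np.asarray(data[response], dtype=float)
    a_vals = np.asarray(data[factor_a])
    b_vals = np.asarray(data[factor_b])
    a_levels = np.unique(a_vals)
    b_levels = np.unique(b_vals)
    ka, kb = a_levels.size, b_levels.size
    if ka < 2 or kb < 2:
        raise ValueError("each factor needs at least 2 levels")

    cell_stats: dict = {}
    for la in a_levels:
        for lb in b_levels:
            cell = y[(a_vals == la) & (b_vals == lb)]
            if cell.size == 0:
                raise ValueError(f"empty cell: {factor_a}={la!r}, {factor_b}={lb!r}")
            if cell.size < 2:
                raise ValueError(
                    f"cell {factor_a}={la!r}, {factor_b}={lb!r} has fewer than 2 replicates"
                )
            cell_stats[(la, lb)] = {
                "n": int(cell.size),
                "mean": float(cell.mean()),
                "sd": float(cell.std(ddof=1)),
            }

    n = y.size
    A = _sum_to_zero_codes(a_levels, a_vals)
    B = _sum_to_zero_codes(b_levels, b_vals)
    AB = np.einsum("ni,nj->nij", A, B).reshape(n, (ka - 1) * (kb - 1))
    intercept = np.ones((n, 1))
    X_full = np.hstack([intercept, A, B, AB])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("singular design")
    sse_full = _sse(X_full, y)
    df_error = n - X_full.shape[1]
    if df_error <= 0:
        raise ValueError("no residual degrees of freedom")
    mse = sse_full / df_error

    if ss_type == "III":
        ss_a = _sse(np.hstack([intercept, B, AB]), y) - sse_full
        ss_b = _sse(np.hstack([intercept, A, AB]), y) - sse_full
    else:  # Type II: main effects tested in the additive model
        sse_additive = _sse(np.hstack([intercept, A, B]), y)
        ss_a = _sse(np.hstack([intercept, B]), y) - sse_additive
        ss_b = _sse(np.hstack([intercept, A]), y) - sse_additive
    ss_ab = _sse(np.hstack([intercept, A, B]), y) - sse_full
    ss_total = float(((y - y.mean()) ** 2).sum())

    effects = {}
    for name, ss, df_num in [
        (factor_a, ss_a, ka - 1),
        (factor_b, ss_b, kb - 1),
        ("interaction", ss_ab, (ka - 1) * (kb - 1)),
    ]:
        ss = max(ss, 0.0)  # guard tiny negative round-off
        f = (ss / df_num) / mse if mse > 0 else 0.0
        p = _f_sf(f, df_num, df_error) if mse > 0 else 1.0
        effects[name] = StatResult(
            "two_way_anova_F", f, (float(df_num), float(df_error)), p,
            extra={"ss": ss, "df": df_num},
        )
    return TwoWayAnovaResult(
        factor_a=factor_a, factor_b=factor_b, effects=effects,
        ss={factor_a: max(ss_a, 0.0), factor_b: max(ss_b, 0.0),
            "interaction": max(ss_ab, 0.0)},
        ss_total=ss_total, ss_error=sse_full, df_error=df_error, mse=mse,
        cell_stats=cell_stats, ss_type=ss_type,
    )


def pairwise_contrasts(
    anova: TwoWayAnovaResult,
    within: str,
    compare: tuple,
) -> pd.DataFrame:
    """Šidák-corrected pairwise contrasts after a two-way ANOVA.

    For each level of the ``within`` factor, compares the two levels of the
    other factor named in ``compare`` with a pooled-error t statistic
    (t = Δmean / sqrt(MSE·(1/n1 + 1/n2)), df = df_error) and applies a
    Šidák adjustment with m = number of contrasts performed — the
    "post-test" convention of the original analysis software.
    """
    if within == anova.factor_a:
        within_idx, across_idx = 0, 1
    elif within == anova.factor_b:
        within_idx, across_idx = 1, 0
    else:
        raise ValueError(f"unknown factor {within!r}")
    lv1, lv2 = compare
    within_levels = sorted({k[within_idx] for k in anova.cell_stats})
    rows = []
    m = len(within_levels)
    for lw in within_levels:
        key1 = [None, None]
        key1[within_idx], key1[across_idx] = lw, lv1
        key2 = [None, None]
        key2[within_idx], key2[across_idx] = lw, lv2
        s1 = anova.cell_stats[tuple(key1)]
        s2 = anova.cell_stats[tuple(key2)]
        diff = s1["mean"] - s2["mean"]
        se = math.sqrt(anova.mse * (1.0 / s1["n"] + 1.0 / s2["n"]))
        t = diff / se if se > 0 else 0.0
        p = min(1.0, 2.0 * _t_sf(abs(t), anova.df_error)) if se > 0 else 1.0
        rows.append({
            within: lw, "mean_1": s1["mean"], "mean_2": s2["mean"],
            "diff": diff, "t": t, "df": anova.df_error, "p": p,
            "p_adj": sidak_adjust(p, m), "m": m,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Šidák
# ---------------------------------------------------------------------------

def sidak_adjust(p: float, m: int) -> float:
    """Šidák-adjusted p-value: 1 − (1 − p)^m, clipped to [0, 1]."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    if p == 1.0:
        return 1.0
    return float(min(1.0, -math.expm1(m * math.log1p(-p))))


# ---------------------------------------------------------------------------
# Mantel–Cox (log-rank)
# ---------------------------------------------------------------------------

def mantel_cox(durations, groups, observed=None) -> StatResult:
    """Mantel–Cox log-rank test over two or more survival groups.

    At every distinct event time the observed deaths per group are
    compared with their hypergeometric expectation given the risk sets;
    the chi-square statistic is (O−E)ᵀ V⁻¹ (O−E) over the first k−1
    groups with df = k−1. Right-censoring is supported through
    ``observed`` (1 = death observed, 0 = censored); by default every
    subject is an event, matching assays run until every fly had died.
    """
    durations = np.asarray(durations, dtype=float)
    groups = np.asarray(groups)
    if observed is None:
        observed = np.ones(durations.size, dtype=bool)
    else:
        observed = np.asarray(observed, dtype=bool)
    if durations.size != groups.size or durations.size != observed.size:
        raise ValueError("durations, groups and observed must be the same length")
    labels, gidx = np.unique(groups, return_inverse=True)
    k = labels.size
    if k < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(gidx, minlength=k)
    if np.any(counts == 0):
        raise ValueError("every group must contain at least one subject")

    event_times = np.unique(durations[observed])
    o_minus_e = np.zeros(k - 1)
    V = np.zeros((k - 1, k - 1))
    for t in event_times:
        at_risk = durations >= t
        n_t = int(at_risk.sum())
        n_i = np.bincount(gidx[at_risk], minlength=k).astype(float)
        dying = observed & (durations == t)
        d_t = int(dying.sum())
        d_i = np.bincount(gidx[dying], minlength=k).astype(float)
        if n_t == 0 or d_t == 0:
            continue
        e_i = d_t * n_i / n_t
        o_minus_e += (d_i - e_i)[: k - 1]
        if n_t > 1:
            c = d_t * (n_t - d_t) / (n_t - 1.0)
            for i in range(k - 1):
                for j in range(k - 1):
                    if i == j:
                        V[i, j] += c * n_i[i] * (n_t - n_i[i]) / n_t ** 2
                    else:
                        V[i, j] -= c * n_i[i] * n_i[j] / n_t ** 2
    if not np.any(V):
        # no variability: identical death-time structure
        return StatResult("mantel_cox", 0.0, float(k - 1), 1.0,
                          extra={"groups": list(labels), "n": counts.tolist()})
    chi2 = float(o_minus_e @ np.linalg.solve(V, o_minus_e))
    chi2 = max(chi2, 0.0)
    p = _chi2_sf(chi2, k - 1)
    return StatResult(
        "mantel_cox", chi2, float(k - 1), p,
        extra={"groups": list(labels), "n": counts.tolist(),
               "o_minus_e": o_minus_e.tolist()},
    )
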