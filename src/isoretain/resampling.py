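"""Resampling tests for survival and single-cell fitness comparisons.

The centrepiece is a Poisson-surrogate bootstrap for colony-forming-unit
(CFU) survival assays: the statistic is the difference Delta between the
total colony counts of the low- and high-expression sorted populations over
all timepoints; the null ("no difference between the populations") is
simulated by redrawing every (population, timepoint, replicate) colony
count from a Poisson distribution whose rate is the pooled mean colony
count at that timepoint.  Companion tests: a one-sided permutation test on
fractions of binary single-cell outcomes, a Mann–Whitney U test (exact for
small samples, tie-corrected normal approximation otherwise) and a
pooled-variance two-sample t test.

Survival tables are plain DataFrames with columns
``population`` ("low"/"high"), ``timepoint_h``, ``replicate``, ``colonies``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidTableError

POPULATIONS = ("low", "high")
SURVIVAL_COLUMNS = ["population", "timepoint_h", "replicate", "colonies"]


def validate_survival_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SURVIVAL_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidTableError(f"survival table missing columns: {missing}")
    pops = set(table["population"].unique())
    if not set(POPULATIONS) <= pops:
        raise InvalidTableError(
            f"survival table must contain populations {POPULATIONS}, found {sorted(pops)}"
        )
    if (table["colonies"] < 0).any():
        raise InvalidTableError("colony counts must be non-negative")
    t_low = set(table.loc[table["population"] == "low", "timepoint_h"])
    t_high = set(table.loc[table["population"] == "high", "timepoint_h"])
    if t_low != t_high:
        raise InvalidTableError("both populations must share the same timepoints")
    if not t_low:
        raise InvalidTableError("survival table has no timepoints")
    return table


@dataclass
class BootstrapResult:
    delta_obs: float
    lambdas: dict[float, float]
    n_surrogates: int
    p_one_sided: float
    p_two_sided: float
    seed: int


def delta_statistic(table: pd.DataFrame) -> float:
    """Delta = total low-population colonies minus total high-population colonies."""
    validate_survival_table(table)
    totals = table.groupby("population")["colonies"].sum()
    return float(totals["low"] - totals["high"])


def poisson_bootstrap_p(
    table: pd.DataFrame,
    n_surrogates: int = 10_000,
    seed: int = 0,
    sided: str = "two",
) -> BootstrapResult:
    """Poisson-surrogate bootstrap p value for the Delta statistic.

    The per-timepoint null rate lambda_t is the mean colony count pooled
    over both populations' replicates at that timepoint (the maximum-
    likelihood rate under the no-difference null).  Each surrogate redraws
    every table cell from Poisson(lambda_t) and recomputes Delta; p values
    carry the add-one guard (r+1)/(n+1).
    """
    validate_survival_table(table)
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    delta_obs = delta_statistic(table)
    lambdas = table.groupby("timepoint_h")["colonies"].mean()
    cell_lambda = table["timepoint_h"].map(lambdas).to_numpy(dtype=float)
    sign = np.where(table["population"].to_numpy() == "low", 1.0, -1.0)

    rng = np.random.default_rng(seed)
    surrogate_counts = rng.poisson(
        lam=cell_lambda, size=(n_surrogates, cell_lambda.size)
    )
    delta_star = surrogate_counts @ sign
    p_one = (np.count_nonzero(delta_star >= delta_obs) + 1) / (n_surrogates + 1)
    p_two = (np.count_nonzero(np.abs(delta_star) >= abs(delta_obs)) + 1) / (
        n_surrogates + 1
    )
    return BootstrapResult(
        delta_obs=delta_obs,
        lambdas={float(t): float(l) for t, l in lambdas.items()},
        n_surrogates=n_surrogates,
        p_one_sided=float(p_one),
        p_two_sided=float(p_two),
        seed=seed,
    )


def permutation_fraction_test(
    flags_a: np.ndarray,
    flags_b: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """One-sided permutation p for fraction(b) - fraction(a) of binary outcomes."""
    a = np.asarray(flags_a, dtype=float)
    b = np.asarray(flags_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    stat_obs = b.mean() - a.mean()
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    stat_star = perms[:, a.size :].mean(axis=1) - perms[:, : a.size].mean(axis=1)
    return float((np.count_nonzero(stat_star >= stat_obs) + 1) / (n_perm + 1))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x: number of (x_i, y_j) pairs with x_i > y_j, half credit for ties."""
    ranks = stats.rankdata(np.concatenate([x, y]))
    r_x = ranks[: x.size].sum()
    return float(r_x - x.size * (x.size + 1) / 2)


def _exact_u_cdf_no_ties(n: int, m: int) -> np.ndarray:
    """Exact null pmf of U without ties.

    The number of rank arrangements with a given U is the coefficient of
    q^U in the Gaussian binomial [n+m, n]_q = prod_k (1-q^(m+k))/(1-q^k);
    the product is built up by polynomial multiplication and stride-k
    prefix sums (exact small-integer arithmetic throughout).
    """
    max_u = n * m
    p = np.zeros(max_u + 1)
    p[0] = 1.0
    for k in range(1, n + 1):
        q = p.copy()
        if m + k <= max_u:
            q[m + k :] -= p[: max_u + 1 - (m + k)]
        for u in range(k, max_u + 1):  # divide by (1 - q^k)
            q[u] += q[u - k]
        p = q
    return p / math.comb(n + m, n)


def _exact_p_with_ties(x: np.ndarray, y: np.ndarray, u_obs: float) -> tuple[float, float]:
    """Enumerate all group assignments of the pooled sample (small n only)."""
    pooled = np.concatenate([x, y])
    n = x.size
    idx = range(pooled.size)
    lows, highs = 0, 0
    total = 0
    mid = x.size * y.size / 2
    for comb in itertools.combinations(idx, n):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(comb)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        total += 1
        if u <= u_obs:
            lows += 1
        if u >= u_obs:
            highs += 1
    p_one = min(lows, highs) / total
    p_two = min(1.0, 2 * min(lows, highs) / total)
    return p_one, p_two


def mann_whitney_u(
    x: np.ndarray, y: np.ndarray, sided: str = "two"
) -> tuple[float, float]:
    """Mann–Whitney U test.

    Exact null distribution when n*m <= 400 (counting recursion without
    ties; full enumeration for small tied samples), otherwise a normal
    approximation with tie-corrected variance and continuity correction.
    The one-sided p is taken in the direction of the observed effect.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    n, m = x.size, y.size
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size

    if n * m <= 400 and not has_ties:
        pmf = _exact_u_cdf_no_ties(n, m)
        cdf = np.cumsum(pmf)
        ui = int(round(u))
        p_low = float(cdf[ui])
        p_high = float(pmf[ui:].sum())
        p_one = min(p_low, p_high)
        p_two = min(1.0, 2 * p_one)
    elif has_ties and math.comb(n + m, n) <= 20_000:
        p_one, p_two = _exact_p_with_ties(x, y, u)
    else:
        mean_u = n * m / 2
        nn = n + m
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (nn * (nn - 1))
        var_u = n * m / 12 * ((nn + 1) - tie_term)
        if var_u <= 0:
            return u, 1.0
        z = (abs(u - mean_u) - 0.5) / math.sqrt(var_u)
        z = max(z, 0.0)
        p_one = float(stats.norm.sf(z))
        p_two = min(1.0, 2 * p_one)
    return u, (p_one if sided == "one" else p_two)


@dataclass
class TTestResult:
    statistic: float
    pvalue: float
    df: int
    degenerate: bool = False


def two_sample_t(x: np.ndarray, y: np.ndarray) -> TTestResult:
    """Two-sided pooled-variance two-sample t test.

    Degenerate inputs (zero pooled variance) are handled explicitly: equal
    means give p = 1; unequal means give the p -> 0 limit with the
    ``degenerate`` flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least 2 observations")
    df = x.size + y.size - 2
    pooled_var = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df
    if pooled_var == 0:
        if x.mean() == y.mean():
            return TTestResult(statistic=0.0, pvalue=1.0, df=df)
        sign = 1.0 if x.mean() > y.mean() else -1.0
        return TTestResult(
            statistic=sign * float("inf"), pvalue=0.0, df=df, degenerate=True
        )
    res = stats.ttest_ind(x, y, equal_var=True)
    return TTestResult(statistic=float(res.statistic), pvalue=float(res.pvalue), df=df)


def survival_curve(table: pd.DataFrame, normalize: bool = False) -> pd.DataFrame:
    """Replicate means and standard errors per population and timepoint."""
    validate_survival_table(table)
    grouped = (
        table.groupby(["population", "timepoint_h"])["colonies"]
        .agg(mean="mean", sem=lambda c: c.sem(), n="count")
        .reset_index()
    )
    if normalize:
        for pop in grouped["population"].unique():
            sel = grouped["population"] == pop
            t0 = grouped.loc[sel, "timepoint_h"].min()
            ref = grouped.loc[sel & (grouped["timepoint_h"] == t0), "mean"].iloc[0]
            grouped.loc[sel, ["mean", "sem"]] /= ref
    return grouped
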