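"""Cross-cohort replication statistics.

pi1 = 1 - pi0 estimates the fraction of true positives among a set of
p-values (Storey's method): pi0(lambda) = #{p > lambda} / (m (1-lambda))
on a lambda grid, extrapolated to lambda -> 1 with a cubic smoothing
spline ("smoother") or read off at lambda = 0.5 ("fixed"). The exact
binomial test is two-sided by the minimum-likelihood rule. The one-sided
two-sample KS test reports the directed sup-difference of empirical CDFs
with the asymptotic tail p = exp(-2 D^2 mn/(m+n)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, stats

logger = logging.getLogger("tqtlkit")

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.96, 0.05), 2)


@dataclass
class Pi1Result:
    pi0: float
    pi1: float
    lambda_grid: np.ndarray
    method: str

    def __post_init__(self) -> None:
        assert 0.0 <= self.pi1 <= 1.0


def estimate_pi1(
    pvalues: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    method: str = "smoother",
) -> Pi1Result:
    """Storey-style pi1 estimate from a vector of p-values.

    ``smoother`` fits a cubic smoothing spline to pi0(lambda) over the
    grid and evaluates it at the largest lambda; ``fixed`` uses
    pi0(0.5). The estimate is clipped to [0, 1]. Fewer than 100 p-values
    triggers a warning (the lambda tail becomes noisy).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size < 100:
        warnings.warn("pi1 estimated from fewer than 100 p-values",
                      stacklevel=2)
    grid = (
        np.asarray(lambda_grid, dtype=float) if lambda_grid is not None
        else DEFAULT_LAMBDA_GRID
    )
    m = p.size
    pi0_grid = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in grid])
    if method == "smoother":
        spline = interpolate.UnivariateSpline(grid, pi0_grid, k=3)
        pi0 = float(spline(grid.max()))
    elif method == "fixed":
        lam = 0.5
        pi0 = float((p > lam).sum() / (m * (1.0 - lam)))
    else:
        raise ValueError(f"unknown method {method!r}")
    pi0 = float(np.clip(pi0, 0.0, 1.0))
    return Pi1Result(pi0=pi0, pi1=1.0 - pi0, lambda_grid=grid, method=method)


def exact_binomial_test(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p-value (minimum-likelihood rule).

    Sums P(X = x) over all outcomes x whose point probability does not
    exceed P(X = k), X ~ Binomial(n, p0).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    return float(stats.binomtest(k, n, p0).pvalue)


def one_sided_ks_test(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    alternative: str,
    method: str = "asymptotic",
    n_permutations: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """One-sided two-sample KS test; returns ``(statistic, p)``.

    ``alternative="greater"`` tests whether ``sample_b`` is stochastically
    greater than ``sample_a`` (right-shifted; D = sup_x F_a(x) - F_b(x));
    ``"less"`` tests the opposite direction. The asymptotic p is
    exp(-2 D^2 mn/(m+n)); ``method="permutation"`` estimates p by
    permuting group labels instead (small samples).
    """
    a = np.sort(np.asarray(sample_a, dtype=float))
    c = np.sort(np.asarray(sample_b, dtype=float))
    if a.size == 0 or c.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("greater", "less"):
        raise ValueError(f"invalid alternative {alternative!r}")

    def directed_stat(x: np.ndarray, y: np.ndarray) -> float:
        pts = np.concatenate([x, y])
        fx = np.searchsorted(x, pts, side="right") / x.size
        fy = np.searchsorted(y, pts, side="right") / y.size
        diff = fx - fy if alternative == "greater" else fy - fx
        return float(max(diff.max(), 0.0))

    d = directed_stat(a, c)
    m, n = a.size, c.size
    if method == "asymptotic":
        p = float(np.exp(-2.0 * d * d * m * n / (m + n)))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([a, c])
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            if directed_stat(np.sort(perm[:m]), np.sort(perm[m:])) >= d - 1e-12:
                hits += 1
        p = (1.0 + hits) / (n_permutations + 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return d, min(p, 1.0)


def ld_structure_correlation(
    r2_pop1: pd.Series, r2_pop2: pd.Series
) -> float:
    """Pearson correlation of two populations' r^2 vectors at one locus.

    Vectors are aligned on their shared variants (those polymorphic in
    both populations, hence present in both series). Returns NaN when
    fewer than 3 shared variants remain or a vector is constant.
    """
    shared = r2_pop1.index.intersection(r2_pop2.index)
    if len(shared) < 3:
        logger.info("LD correlation: fewer than 3 shared polymorphic variants")
        return float("nan")
    x = r2_pop1.loc[shared].to_numpy(dtype=float)
    y = r2_pop2.loc[shared].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        logger.info("LD correlation undefined: constant r^2 vector")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def effect_size_concordance(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    group_labels: pd.Series | None = None,
) -> pd.DataFrame:
    """Effect-size concordance between two cohorts at shared tests.

    Records need columns ``feature_id, variant_id, ref, alt, beta``.
    Pairs are joined on (feature, variant); effects are aligned to the
    same counted allele — matching ref/alt kept as-is, swapped ref/alt
    flips the sign of cohort B's effect, any other allele combination is
    dropped with a log entry. Returns Pearson rho, least-squares slope,
    and pair count per group (plus an ``all`` row).
    """
    merged = records_a.merge(
        records_b, on=["feature_id", "variant_id"], suffixes=("_a", "_b")
    )
    same = (merged["ref_a"] == merged["ref_b"]) & (
        merged["alt_a"] == merged["alt_b"]
    )
    flipped = (merged["ref_a"] == merged["alt_b"]) & (
        merged["alt_a"] == merged["ref_b"]
    )
    n_drop = int((~(same | flipped)).sum())
    if n_drop:
        logger.info("concordance: %d pairs with irreconcilable alleles dropped",
                    n_drop)
    merged = merged.loc[same | flipped].copy()
    merged.loc[flipped[same | flipped], "beta_b"] *= -1.0
    if len(merged) < 3:
        raise ValueError("fewer than 3 shared feature-variant pairs")

    if group_labels is not None:
        merged["group"] = merged["feature_id"].map(group_labels)
    else:
        merged["group"] = "all"

    def _stats(df: pd.DataFrame) -> pd.Series:
        x = df["beta_a"].to_numpy(float)
        y = df["beta_b"].to_numpy(float)
        if len(df) < 3 or np.std(x) == 0:
            return pd.Series({"rho": np.nan, "slope": np.nan, "n": len(df)})
        rho = float(np.corrcoef(x, y)[0, 1])
        slope = float(np.polyfit(x, y, 1)[0])
        return pd.Series({"rho": rho, "slope": slope, "n": len(df)})

    per_group = merged.groupby("group").apply(_stats, include_groups=False)
    overall = _stats(merged).rename("all")
    if "all" not in per_group.index:
        per_group = pd.concat([per_group, overall.to_frame().T])
    per_group["n"] = per_group["n"].astype(int)
    return per_group


def classify_shared_independent(
    conditional_flags: pd.Series, records: pd.DataFrame | None = None
) -> pd.Series | pd.DataFrame:
    """Label features "independent" (still significant after conditioning)
    or "shared" (signal removed by conditioning).

    With ``records`` supplied, the labels are joined onto the association
    table (column ``replication_class``; features absent from the
    conditional output get a missing label).
    """
    labels = conditional_flags.map({True: "independent", False: "shared"})
    labels.name = "replication_class"
    if records is None:
        return labels
    out = records.copy()
    out["replication_class"] = out["feature_id"].map(labels)
    return out
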