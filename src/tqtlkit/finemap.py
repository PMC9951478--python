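"""Wakefield approximate Bayes factors, causal posteriors, credible sets.

Under a single-causal-variant assumption with a N(0, W) prior on the
effect, the approximate Bayes factor for a variant with Wald statistic
z = beta/se and V = se^2 is

    ABF = sqrt(1 - r) * exp(z^2 r / 2),   r = W / (V + W),

so log ABF = (log(1 - r) + z^2 r) / 2. When only a p-value is available,
|z| is recovered from the two-sided p and V is approximated by
1 / (2 n f (1 - f)) with f the allele frequency (the sign of z does not
enter the ABF). Per-variant causal posteriors are the ABFs normalized
over the feature's tested variants, and the 90% credible set is the
minimal PP-descending prefix whose cumulative posterior mass strictly
exceeds the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

logger = logging.getLogger("tqtlkit")

DEFAULT_PRIOR_SD = 0.15     # prior effect SD on a unit-variance phenotype
Z_CAP = 40.0                # |z| cap used when p underflows to 0

# strict ">" mass rule, guarded against float round-off in the cumsum
_MASS_EPS = 1e-12


def approximate_bayes_factor(
    beta: np.ndarray | None = None,
    se: np.ndarray | None = None,
    p: np.ndarray | None = None,
    maf: np.ndarray | None = None,
    n: int | None = None,
    prior_sd: float = DEFAULT_PRIOR_SD,
) -> np.ndarray:
    """log approximate Bayes factor per variant.

    Summary mode needs ``beta`` and ``se``; p-value mode needs ``p``,
    ``maf`` and ``n`` and is used as the fallback when effect estimates
    are unavailable. ``prior_sd`` is the SD of the effect prior (W =
    prior_sd^2).
    """
    w = float(prior_sd) ** 2
    if beta is not None and se is not None:
        beta = np.asarray(beta, dtype=float)
        se = np.asarray(se, dtype=float)
        if (se <= 0).any():
            raise ValueError("standard errors must be positive")
        z = beta / se
        v = se ** 2
    elif p is not None and maf is not None and n is not None:
        p = np.asarray(p, dtype=float)
        f = np.asarray(maf, dtype=float)
        if ((f <= 0) | (f >= 1)).any():
            raise ValueError("allele frequency must lie strictly in (0, 1)")
        with np.errstate(divide="ignore"):
            z = -stats.norm.ppf(p / 2.0)
        z = np.minimum(z, Z_CAP)
        v = 1.0 / (2.0 * n * f * (1.0 - f))
    else:
        raise ValueError("need either (beta, se) or (p, maf, n)")
    r = w / (v + w)
    return 0.5 * (np.log1p(-r) + z ** 2 * r)


def causal_posteriors(log_abf: np.ndarray) -> np.ndarray:
    """Normalize log ABFs into per-variant causal posteriors (sum to 1)."""
    log_abf = np.asarray(log_abf, dtype=float)
    if log_abf.size == 0:
        raise ValueError("need at least one variant")
    return np.exp(log_abf - logsumexp(log_abf))


def posterior_table(
    feature_id: str,
    variant_ids: list[str],
    log_abf: np.ndarray,
    p: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-variant posterior records for one feature."""
    pp = causal_posteriors(log_abf)
    return pd.DataFrame(
        {
            "feature_id": feature_id,
            "variant_id": variant_ids,
            "log_abf": np.asarray(log_abf, dtype=float),
            "PP": pp,
            "p": np.asarray(p, dtype=float) if p is not None else np.nan,
        }
    )


@dataclass
class CredibleSet:
    """Minimal variant set whose posterior mass strictly exceeds ``mass``."""

    feature_id: str
    variant_ids: list[str]
    cumulative_mass: float
    mass: float = 0.9

    @property
    def size(self) -> int:
        return len(self.variant_ids)


def build_credible_set(
    posteriors: pd.DataFrame, mass: float = 0.9
) -> CredibleSet:
    """Credible set from one feature's posterior table.

    Variants are sorted by PP descending (ties broken by smaller p, then
    by variant id) and the shortest prefix whose cumulative PP strictly
    exceeds ``mass`` is taken.
    """
    if posteriors.empty:
        raise ValueError("empty posterior table")
    tab = posteriors.sort_values(
        ["PP", "p", "variant_id"], ascending=[False, True, True],
        kind="mergesort",
    )
    cum = tab["PP"].cumsum().to_numpy()
    above = np.flatnonzero(cum > mass + _MASS_EPS)
    size = int(above[0]) + 1 if above.size else len(tab)
    chosen = tab.iloc[:size]
    return CredibleSet(
        feature_id=str(posteriors["feature_id"].iloc[0]),
        variant_ids=list(chosen["variant_id"]),
        cumulative_mass=float(cum[size - 1]),
        mass=mass,
    )


def credible_sets_from_scan(
    records: pd.DataFrame,
    mass: float = 0.9,
    prior_sd: float = DEFAULT_PRIOR_SD,
) -> tuple[pd.DataFrame, dict[str, CredibleSet]]:
    """Fine-map every feature in a cis-scan result.

    Returns the concatenated posterior table (with an ``in_credible_set``
    flag) and the per-feature credible sets.
    """
    tables, sets = [], {}
    for fid, grp in records.groupby("feature_id", sort=False):
        log_abf = approximate_bayes_factor(
            beta=grp["beta"].to_numpy(), se=grp["se"].to_numpy(),
            prior_sd=prior_sd,
        )
        tab = posterior_table(fid, list(grp["variant_id"]), log_abf,
                              grp["p"].to_numpy())
        cs = build_credible_set(tab, mass=mass)
        tab["in_credible_set"] = tab["variant_id"].isin(cs.variant_ids)
        tables.append(tab)
        sets[fid] = cs
    return pd.concat(tables, ignore_index=True), sets


def credible_set_overlap(
    sets_a: dict[str, CredibleSet],
    sets_b: dict[str, CredibleSet],
    posteriors_a: pd.DataFrame | None = None,
    posteriors_b: pd.DataFrame | None = None,
    min_pp: float = 0.0,
) -> tuple[pd.Series, dict[str, float]]:
    """Per-feature credible-set overlap between two analyses.

    A feature overlaps iff the variant-id intersection of its two sets is
    non-empty. With ``min_pp > 0`` and posterior tables supplied, each set
    is first restricted to variants with PP >= min_pp (e.g. 0.1 for a
    "greater than 10% causal probability" comparison). Returns the
    boolean flags and summary counts.
    """
    shared = sorted(set(sets_a) & set(sets_b))
    flags = {}
    for fid in shared:
        va, vb = set(sets_a[fid].variant_ids), set(sets_b[fid].variant_ids)
        if min_pp > 0.0:
            if posteriors_a is None or posteriors_b is None:
                raise ValueError("min_pp filtering needs both posterior tables")
            for tab, vs in ((posteriors_a, va), (posteriors_b, vb)):
                sub = tab[(tab["feature_id"] == fid) & (tab["PP"] >= min_pp)]
                vs.intersection_update(sub["variant_id"])
        flags[fid] = bool(va & vb)
    flag_series = pd.Series(flags, dtype=bool, name="overlap")
    n = len(flag_series)
    summary = {
        "n_features": float(n),
        "n_overlap": float(flag_series.sum()) if n else 0.0,
        "fraction_overlap": float(flag_series.mean()) if n else float("nan"),
    }
    return flag_series, summary
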