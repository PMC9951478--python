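"""Gene-level selection scans and matched-background enrichment tests.

Each feature's fine-mapping posteriors turn per-SNP statistics into one
locus score: the causal-probability-weighted average

    score = sum_p PP_p * stat_p

(applied to Hudson F_ST, the polarized d-statistic, and PBS). The
background-selection control permutes the statistic across the locus's
variants while holding the posterior weights fixed; the empirical p-value
uses the add-one convention (1 + #{null >= observed}) / (B + 1) so it is
never zero. Global candidates must exceed the 99th percentile of the
genome-wide per-SNP F_ST and have permutation p below 0.01;
population-specific candidates must exceed the 99.5th percentile of both
the genome-wide d and PBS distributions.

The F_ST-outlier enrichment test follows the matched-background design:
each lead SNP is matched to a random background SNP from the same MAF bin
(width 0.05) and LD-set-size bin, and the fraction of max-F_ST-in-LD-set
outliers among leads is compared with the matched null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("tqtlkit")

LD_COUNT_BIN_EDGES = (0, 1, 2, 5, 10, 20, 50)   # {0},{1,2},(2,5],(5,10],(10,20],(20,50],>50


@dataclass
class MatchingBins:
    """Binning used to match background SNPs to lead SNPs.

    MAF bins have fixed width (default 0.05); LD-set-size bins follow the
    fixed edges {0}, {1,2}, (2,5], (5,10], (10,20], (20,50], >50 counting
    SNPs in LD excluding the lead itself.
    """

    maf_bin_width: float = 0.05
    ld_count_edges: tuple[int, ...] = LD_COUNT_BIN_EDGES

    def maf_bin(self, maf: np.ndarray) -> np.ndarray:
        maf = np.asarray(maf, dtype=float)
        return np.minimum(
            (maf / self.maf_bin_width).astype(int),
            int(0.5 / self.maf_bin_width) - 1,
        )

    def ld_bin(self, n_in_ld: np.ndarray) -> np.ndarray:
        n = np.asarray(n_in_ld, dtype=float)
        # bins: ==0 -> 0; 1..2 -> 1; (2,5] -> 2; (5,10] -> 3; ...
        edges = np.asarray(self.ld_count_edges[1:], dtype=float)  # 1,2,5,10,20,50
        out = np.zeros(n.shape, dtype=int)
        out[n >= 1] = 1
        for b, hi in enumerate(edges[1:], start=1):   # 2,5,10,20,50
            out[n > hi] = b + 1
        return out


def weighted_locus_score(
    pp: np.ndarray, stat: np.ndarray
) -> float:
    """Posterior-weighted locus score sum_p PP_p * stat_p.

    Variants with a missing statistic are dropped and the posteriors
    renormalized over the remainder (logged). The score always lies
    within [min, max] of the locus's defined statistics.
    """
    pp = np.asarray(pp, dtype=float)
    stat = np.asarray(stat, dtype=float)
    ok = np.isfinite(stat)
    if not ok.any():
        raise ValueError("all per-variant statistics missing at this locus")
    if not ok.all():
        logger.info("locus score: %d variants with missing statistic dropped",
                    int((~ok).sum()))
        pp, stat = pp[ok], stat[ok]
        pp = pp / pp.sum()
    return float(pp @ stat)


def locus_permutation_test(
    pp: np.ndarray,
    stat: np.ndarray,
    b: int = 10_000,
    seed: int | np.random.Generator = 0,
    exhaustive: bool = False,
) -> tuple[float, float]:
    """Permutation p-value for one locus's weighted score.

    The statistic vector is permuted across the locus's variants ``b``
    times against the fixed posterior vector; empirical p =
    (1 + #{null >= observed}) / (B + 1). With ``exhaustive=True`` all
    n! permutations are enumerated (loci of <= 8 variants).

    Returns ``(observed_score, empirical_p)``.
    """
    pp = np.asarray(pp, dtype=float)
    stat = np.asarray(stat, dtype=float)
    if pp.size < 2:
        raise ValueError("need >= 2 variants for a locus permutation test")
    ok = np.isfinite(stat)
    if not ok.all():
        pp, stat = pp[ok], stat[ok]
        pp = pp / pp.sum()
    observed = float(pp @ stat)
    if exhaustive:
        from itertools import permutations

        if pp.size > 8:
            raise ValueError("exhaustive enumeration limited to 8 variants")
        null = np.fromiter(
            (pp @ stat[list(perm)] for perm in permutations(range(pp.size))),
            dtype=float,
        )
        n_null = null.size
    else:
        if b <= 0:
            raise ValueError("B must be positive")
        rng = (
            seed if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        perms = np.argsort(rng.random((b, stat.size)), axis=1)
        null = stat[perms] @ pp
        n_null = b
    tol = 1e-12 * max(1.0, abs(observed))
    p = (1.0 + np.sum(null >= observed - tol)) / (n_null + 1.0)
    return observed, float(p)


def call_candidates_global(
    scores: pd.DataFrame,
    snp_fst_values: np.ndarray,
    pct: float = 0.99,
    emp_alpha: float = 0.01,
) -> pd.Series:
    """Global selection candidates from weighted F_ST scores.

    ``scores`` needs columns ``weighted_fst`` and ``empirical_p``. A
    feature is a candidate iff its weighted F_ST exceeds the ``pct``
    quantile of the genome-wide per-SNP F_ST values AND its permutation
    p-value is below ``emp_alpha``.
    """
    threshold = float(np.nanquantile(np.asarray(snp_fst_values, float), pct))
    flags = (scores["weighted_fst"] > threshold) & (
        scores["empirical_p"] < emp_alpha
    )
    flags.name = "candidate_global"
    return flags


def call_candidates_population(
    weighted_d: pd.Series,
    weighted_pbs: pd.Series,
    snp_d: np.ndarray,
    snp_pbs: np.ndarray,
    pct: float = 0.995,
) -> pd.Series:
    """Population-specific candidates: both d and PBS above the ``pct``
    quantile of their genome-wide per-SNP distributions."""
    d_thr = float(np.nanquantile(np.asarray(snp_d, float), pct))
    pbs_thr = float(np.nanquantile(np.asarray(snp_pbs, float), pct))
    flags = (weighted_d > d_thr) & (weighted_pbs > pbs_thr)
    flags.name = "candidate_population"
    return flags


# ---------------------------------------------------------------------------
# Matched-background F_ST outlier enrichment
# ---------------------------------------------------------------------------

def _nearest_nonempty_key(
    groups: Mapping[tuple[int, int], np.ndarray], key: tuple[int, int]
) -> tuple[int, int]:
    """The requested bin key, or the nearest non-empty bin's key."""
    if key in groups and len(groups[key]):
        return key
    best, best_dist = None, None
    for other, pool in groups.items():
        if not len(pool):
            continue
        dist = abs(other[0] - key[0]) + abs(other[1] - key[1])
        if best_dist is None or dist < best_dist:
            best, best_dist = other, dist
    if best is None:
        raise ValueError("background pool is empty")
    logger.warning("empty matching bin %s: nearest non-empty bin %s used",
                   key, best)
    return best


def _binned_null_draws(
    groups: Mapping[tuple[int, int], np.ndarray],
    need: Mapping[tuple[int, int], int],
    rng: np.random.Generator,
) -> np.ndarray:
    """One null replicate: per bin, draw ``need`` pool rows without
    replacement (with replacement only when the bin pool is too small)."""
    picks = []
    for key, c in need.items():
        pool = groups[key]
        if len(pool) >= c:
            picks.append(rng.choice(pool, size=c, replace=False))
        else:
            picks.append(rng.choice(pool, size=c, replace=True))
    return np.concatenate(picks)


def fst_outlier_enrichment(
    lead_variants: Sequence[str],
    ld_sets: Mapping[str, Sequence[str]],
    snp_fst: pd.Series,
    snp_maf: pd.Series,
    outlier_threshold: float | None = None,
    bins: MatchingBins | None = None,
    b: int = 10_000,
    seed: int | np.random.Generator = 0,
    pct: float = 0.99,
) -> dict:
    """Enrichment of F_ST outliers among lead-SNP LD sets.

    ``ld_sets`` maps every variant (leads and background pool alike) to
    the ids of SNPs in LD with it, the variant itself included. The
    observed statistic is the fraction of leads whose maximum F_ST over
    their LD set exceeds ``outlier_threshold`` (default: the ``pct``
    quantile of all per-SNP F_ST values). Each null replicate replaces
    every lead by a random background SNP from the same MAF x LD-set-size
    bin (without replacement within a replicate; leads excluded from the
    pool; empty bins fall back to the nearest non-empty bin) and
    recomputes the fraction. Empirical p is add-one.
    """
    bins = bins or MatchingBins()
    if b <= 0:
        raise ValueError("B must be positive")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    fst = snp_fst.astype(float)
    if outlier_threshold is None:
        outlier_threshold = float(np.nanquantile(fst.to_numpy(), pct))

    def max_in_ld(vid: str) -> float:
        members = ld_sets.get(vid, [vid])
        vals = fst.reindex(members).to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        return float(vals.max()) if vals.size else float("nan")

    max_fst = pd.Series({v: max_in_ld(v) for v in ld_sets}, dtype=float)
    n_in_ld = pd.Series({v: len(ld_sets[v]) - 1 for v in ld_sets})

    leads = list(lead_variants)
    observed = float(np.mean(max_fst.reindex(leads) > outlier_threshold))

    pool_ids = [v for v in ld_sets if v not in set(leads)]
    if not pool_ids:
        raise ValueError("background pool is empty")
    pool_key = np.stack(
        [bins.maf_bin(snp_maf.reindex(pool_ids).to_numpy(dtype=float)),
         bins.ld_bin(n_in_ld.reindex(pool_ids).to_numpy())],
        axis=1,
    )
    pool_max = max_fst.reindex(pool_ids).to_numpy(dtype=float)
    groups: dict[tuple[int, int], np.ndarray] = {}
    for key in {tuple(k) for k in pool_key}:
        groups[key] = pool_max[(pool_key == key).all(axis=1)]

    lead_keys = [
        (int(bins.maf_bin(np.array([snp_maf[v]]))[0]),
         int(bins.ld_bin(np.array([n_in_ld[v]]))[0]))
        for v in leads
    ]
    need: dict[tuple[int, int], int] = {}
    for key in lead_keys:
        key = _nearest_nonempty_key(groups, key)
        need[key] = need.get(key, 0) + 1

    null = np.empty(b)
    for rep in range(b):
        drawn = _binned_null_draws(groups, need, rng)
        null[rep] = np.mean(drawn > outlier_threshold)
    p = (1.0 + np.sum(null >= observed - 1e-12)) / (b + 1.0)
    return {
        "observed_fraction": observed,
        "null_fractions": null,
        "empirical_p": float(p),
        "outlier_threshold": float(outlier_threshold),
    }


# ---------------------------------------------------------------------------
# Annotation enrichment with matched backgrounds
# ---------------------------------------------------------------------------

def _annotate_membership(
    pos: np.ndarray, intervals: Sequence[tuple[int, int]]
) -> np.ndarray:
    """Membership of 1-based positions in half-open [start, end) intervals."""
    if not len(intervals):
        return np.zeros(len(pos), dtype=bool)
    arr = np.asarray(sorted(intervals), dtype=float)
    starts, ends = arr[:, 0], arr[:, 1]
    idx = np.searchsorted(starts, pos - 1, side="right") - 1
    ok = idx >= 0
    member = np.zeros(len(pos), dtype=bool)
    member[ok] = (pos[ok] - 1) < ends[idx[ok]]
    return member


def annotation_enrichment(
    qtl_variants: pd.DataFrame,
    pool: pd.DataFrame,
    annotations: Mapping[str, Sequence[tuple[int, int]]],
    bins: MatchingBins | None = None,
    n_distance_bins: int = 10,
    b: int = 10_000,
    seed: int | np.random.Generator = 0,
    exclude_qtl_from_pool: bool = True,
) -> pd.DataFrame:
    """Matched-background functional-annotation enrichment.

    ``qtl_variants`` and ``pool`` need columns ``id, pos, maf,
    tss_distance``. Backgrounds are matched on MAF (bins of width 0.05)
    and on TSS distance (quantile bins over the pooled distances). Per
    replicate, one matched background SNP is drawn per QTL SNP (without
    replacement within the replicate) and each category's score is
    log((#QTL in category + 1) / (#background in category + 1)); the +1
    pseudocount keeps the ratio defined at zero counts. Returns
    per-category mean score and an add-one two-sided empirical p for a
    shift away from zero; the replicate score distributions sit in
    ``.attrs["score_distributions"]``.
    """
    bins = bins or MatchingBins()
    if b <= 0:
        raise ValueError("B must be positive")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if exclude_qtl_from_pool:
        pool = pool.loc[~pool["id"].isin(set(qtl_variants["id"]))]
    pool = pool.reset_index(drop=True)
    if pool.empty:
        raise ValueError("background pool is empty after excluding QTL SNPs")

    all_dist = np.concatenate(
        [qtl_variants["tss_distance"].to_numpy(float),
         pool["tss_distance"].to_numpy(float)]
    )
    edges = np.unique(np.quantile(all_dist, np.linspace(0, 1, n_distance_bins + 1)))

    def keys(df: pd.DataFrame) -> np.ndarray:
        mb = bins.maf_bin(df["maf"].to_numpy(float))
        db = np.clip(
            np.searchsorted(edges, df["tss_distance"].to_numpy(float),
                            side="right") - 1,
            0, len(edges) - 2,
        )
        return np.stack([mb, db], axis=1)

    cats = list(annotations)
    qtl_member = {
        cat: _annotate_membership(qtl_variants["pos"].to_numpy(int), ivals)
        for cat, ivals in annotations.items()
    }
    # pool rows per bin, as category-membership matrices for fast counting
    pool_member = np.stack(
        [_annotate_membership(pool["pos"].to_numpy(int), annotations[cat])
         for cat in cats], axis=1,
    )
    pool_keys = keys(pool)
    groups: dict[tuple[int, int], np.ndarray] = {}
    member_by_bin: dict[tuple[int, int], np.ndarray] = {}
    for key in {tuple(k) for k in pool_keys}:
        rows = np.flatnonzero((pool_keys == key).all(axis=1))
        groups[key] = rows
        member_by_bin[key] = pool_member[rows]

    need: dict[tuple[int, int], int] = {}
    for key in (tuple(k) for k in keys(qtl_variants)):
        key = _nearest_nonempty_key(groups, key)
        need[key] = need.get(key, 0) + 1

    n_qtl_in = {cat: int(m.sum()) for cat, m in qtl_member.items()}
    scores = {cat: np.empty(b) for cat in cats}
    for rep in range(b):
        bg_counts = np.zeros(len(cats))
        for key, c in need.items():
            members = member_by_bin[key]
            if len(members) >= c:
                rows = rng.choice(len(members), size=c, replace=False)
            else:
                rows = rng.choice(len(members), size=c, replace=True)
            bg_counts += members[rows].sum(axis=0)
        for ci, cat in enumerate(cats):
            scores[cat][rep] = np.log(
                (n_qtl_in[cat] + 1) / (bg_counts[ci] + 1)
            )

    rows = []
    for cat in annotations:
        s = scores[cat]
        p_hi = (1.0 + np.sum(s <= 0)) / (b + 1.0)
        p_lo = (1.0 + np.sum(s >= 0)) / (b + 1.0)
        rows.append(
            {
                "category": cat,
                "n_qtl_in_category": n_qtl_in[cat],
                "mean_score": float(s.mean()),
                "empirical_p": float(min(1.0, 2.0 * min(p_hi, p_lo))),
            }
        )
    out = pd.DataFrame(rows).set_index("category")
    out.attrs["score_distributions"] = scores
    return out
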