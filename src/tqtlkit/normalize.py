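"""Feature filtering, two-stage quantile normalization, hidden factors.

The normalization is the GTEx-style two-stage procedure: each sample's
phenotype distribution is first quantile-normalized to the across-sample
mean distribution, then each feature is rank-transformed to the standard
normal. Hidden expression covariates are inferred as principal components
of the feature-centered matrix, with the number of factors chosen by the
discovery-maximizing grid search (the k giving the most FDR-significant
features wins; ties go to the smallest k).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CovariateMatrix, PhenotypeMatrix

logger = logging.getLogger("tqtlkit")


@dataclass
class FilterThresholds:
    """Phenotype feature-filter thresholds.

    Expression features are kept when reads exceed ``expr_min_reads``
    (strictly) in at least ``expr_min_individuals`` samples and mean TPM
    strictly exceeds ``expr_min_mean_tpm``. Introns are kept when at most
    ``intron_max_zero_individuals`` samples have zero reads and the
    containing cluster has at least ``cluster_min_reads`` reads in at
    least ``cluster_min_individuals`` samples with strictly fewer than
    ``cluster_max_zero_individuals`` zero-read samples.
    """

    expr_min_reads: int = 5
    expr_min_individuals: int = 20
    expr_min_mean_tpm: float = 0.1
    intron_max_zero_individuals: int = 5
    cluster_min_reads: int = 20
    cluster_min_individuals: int = 100
    cluster_max_zero_individuals: int = 10

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative")


def filter_expression_features(
    counts: pd.DataFrame,
    tpm: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
    biotypes: pd.Series | None = None,
    allowed_biotypes: tuple[str, ...] = ("protein_coding", "lncRNA"),
) -> list[str]:
    """Expression features passing the read-support and mean-TPM filters.

    When a ``biotypes`` series (feature id -> biotype) is supplied, only
    features with an allowed biotype are considered.
    """
    t = thresholds or FilterThresholds()
    if not counts.index.equals(tpm.index) or not counts.columns.equals(tpm.columns):
        raise ValueError("counts and TPM matrices must share features and samples")
    enough_reads = (counts > t.expr_min_reads).sum(axis=1) >= t.expr_min_individuals
    enough_tpm = tpm.mean(axis=1) > t.expr_min_mean_tpm
    keep = enough_reads & enough_tpm
    if biotypes is not None:
        keep &= counts.index.to_series().map(biotypes).isin(allowed_biotypes)
    return list(counts.index[keep])


def filter_splicing_features(
    junction_counts: pd.DataFrame,
    cluster_map: pd.Series,
    thresholds: FilterThresholds | None = None,
) -> list[str]:
    """Introns passing the per-intron and per-cluster read-support filters.

    ``cluster_map`` maps intron id -> cluster id; cluster totals are the
    per-sample sums of member junction counts.
    """
    t = thresholds or FilterThresholds()
    missing = junction_counts.index.difference(cluster_map.index)
    if len(missing):
        raise ValueError(f"introns without cluster assignment: {list(missing)[:5]}")
    clusters = junction_counts.index.map(cluster_map)
    cluster_totals = junction_counts.groupby(clusters).sum()

    cluster_reads_ok = (
        (cluster_totals >= t.cluster_min_reads).sum(axis=1) >= t.cluster_min_individuals
    )
    cluster_zeros_ok = (
        (cluster_totals == 0).sum(axis=1) < t.cluster_max_zero_individuals
    )
    cluster_ok = cluster_reads_ok & cluster_zeros_ok

    intron_ok = (
        (junction_counts == 0).sum(axis=1) <= t.intron_max_zero_individuals
    )
    keep = intron_ok & pd.Series(clusters, index=junction_counts.index).map(
        cluster_ok
    ).astype(bool)
    return list(junction_counts.index[keep])


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------

def _quantile_normalize_to_reference(
    matrix: np.ndarray, reference: np.ndarray
) -> np.ndarray:
    """Map each column's order statistics onto ``reference``.

    Ties within a column receive the mean of the reference values their
    positions span.
    """
    out = np.empty_like(matrix, dtype=float)
    n_feat = matrix.shape[0]
    for j in range(matrix.shape[1]):
        col = matrix[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty(n_feat)
        mapped[order] = reference
        # average reference values over tie groups
        sorted_vals = col[order]
        i = 0
        while i < n_feat:
            k = i
            while k + 1 < n_feat and sorted_vals[k + 1] == sorted_vals[i]:
                k += 1
            if k > i:
                mapped[order[i:k + 1]] = reference[i:k + 1].mean()
            i = k + 1
        out[:, j] = mapped
    return out


def rank_to_normal(
    values: np.ndarray, axis: int = 1, offset: str = "half"
) -> np.ndarray:
    """Rank-transform to standard-normal quantiles along ``axis``.

    ``offset="half"`` uses Phi^-1((r - 0.5)/n); ``offset="blom"`` uses
    Phi^-1((r - 3/8)/(n + 1/4)). Ties get average ranks.
    """
    values = np.asarray(values, dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, axis, values)
    n = values.shape[axis]
    if offset == "half":
        grid = (ranks - 0.5) / n
    elif offset == "blom":
        grid = (ranks - 3.0 / 8.0) / (n + 0.25)
    else:
        raise ValueError(f"unknown offset convention: {offset!r}")
    return stats.norm.ppf(grid)


def two_stage_quantile_normalize(
    pm: PhenotypeMatrix, offset: str = "half"
) -> PhenotypeMatrix:
    """Two-stage quantile normalization of a raw phenotype matrix.

    Stage 1 maps every sample's distribution onto the across-sample mean
    order statistics; stage 2 rank-transforms each feature to the standard
    normal. Features constant across samples come out all-zero and are
    recorded in ``constant_features``.
    """
    values = pm.values.to_numpy(dtype=float)
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need at least 2 features and 2 samples")

    reference = np.sort(values, axis=0).mean(axis=1)
    stage1 = _quantile_normalize_to_reference(values, reference)
    stage2 = rank_to_normal(stage1, axis=1, offset=offset)

    constant_mask = np.array(
        [np.unique(values[i]).size == 1 for i in range(values.shape[0])]
    )
    constant = list(pm.features["id"].iloc[np.flatnonzero(constant_mask)])
    if constant:
        # a constant feature carries no rank information; force exact zeros
        # (stage 1 can otherwise break the constancy through the sample maps)
        stage2[constant_mask] = 0.0
        logger.warning("%d features constant across samples; output all zeros",
                       len(constant))
    out = pd.DataFrame(stage2, index=pm.values.index, columns=pm.values.columns)
    return PhenotypeMatrix(values=out, features=pm.features.copy(),
                           norm_state="qn", constant_features=constant)


# ---------------------------------------------------------------------------
# Hidden factors
# ---------------------------------------------------------------------------

def infer_hidden_factors(pm: PhenotypeMatrix, k: int) -> CovariateMatrix:
    """Top-k principal-component sample scores of the phenotype matrix.

    The matrix is feature-centered; components are ordered by variance
    explained, and each is sign-fixed so its largest-magnitude feature
    loading is positive.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    values = pm.values.to_numpy(dtype=float)
    n_feat, n_samp = values.shape
    if k >= min(n_feat, n_samp):
        raise ValueError("k must be < min(n_features, n_samples)")
    centered = values - values.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = vt[:k].T * s[:k]          # samples x k
    for c in range(k):
        pivot = np.argmax(np.abs(u[:, c]))
        if u[pivot, c] < 0:
            scores[:, c] *= -1.0
    cols = [f"PC{c + 1}" for c in range(k)]
    return CovariateMatrix(
        pd.DataFrame(scores, index=pm.values.columns, columns=cols)
    )


def select_factor_count(
    qn_phenotypes: PhenotypeMatrix,
    grid: Sequence[int],
    discovery_fn: Callable[[CovariateMatrix | None], int],
) -> tuple[int, dict[int, int]]:
    """Grid-search the hidden-factor count that maximizes discoveries.

    ``discovery_fn`` receives the inferred-factor covariates for a given k
    (``None`` for k = 0) and returns the number of FDR-significant
    features; the k with the most discoveries wins, ties going to the
    smallest k. Returns the chosen k and the per-k discovery counts.
    """
    grid = sorted(set(int(k) for k in grid))
    if not grid:
        raise ValueError("empty factor grid")
    if any(k < 0 for k in grid):
        raise ValueError("factor counts must be non-negative")
    if grid == [0]:
        return 0, {}
    counts: dict[int, int] = {}
    for k in grid:
        factors = infer_hidden_factors(qn_phenotypes, k) if k > 0 else None
        counts[k] = int(discovery_fn(factors))
        logger.info("factor grid search: k=%d -> %d discoveries", k, counts[k])
    best = max(counts.values())
    chosen = min(k for k, c in counts.items() if c == best)
    return chosen, counts
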