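"""Population-genetic statistics: allele frequencies, Hudson F_ST, PBS,
the polarized d-statistic, and LD r-squared.

Per-variant Hudson F_ST between two populations with sample allele
frequencies p1, p2 and allele counts n1, n2 is

    num = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

and the aggregate over a variant set is the ratio of averages
sum(num)/sum(den). Per-variant values may be negative; they are kept for
the d-statistic and enrichment work but clamped at zero inside the PBS
branch-length log T = -log(1 - F_ST).

The polarized d-statistic for focal population i at one variant is

    d_i = | sum_{j != i} s_j (F_ST^ij - E[F_ST^ij]) / sd[F_ST^ij] |

with s_j = +1 if p_i >= p_j else -1, standardized by the genome-wide mean
and SD of the pairwise F_ST. The polarization stops variants that are at
intermediate frequency in the focal population but differentiated
elsewhere from scoring as focal outliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeDataset

logger = logging.getLogger("tqtlkit")


@dataclass
class PopulationFrequencies:
    """Per-population ALT-allele frequencies and allele counts.

    ``freq`` and ``count`` are frames of shape (variants x populations);
    ``count`` holds 2 x the number of non-missing diploids. Frequencies
    are NaN where a population has no called genotype at a variant.
    """

    freq: pd.DataFrame
    count: pd.DataFrame

    @property
    def populations(self) -> list[str]:
        return list(self.freq.columns)


def population_allele_frequencies(
    genotypes: GenotypeDataset,
) -> PopulationFrequencies:
    """Observed ALT-allele frequency and allele count per population."""
    pops = genotypes.populations
    freq_cols, count_cols = {}, {}
    for pop in pd.unique(pops):
        rows = np.flatnonzero((pops == pop).to_numpy())
        sub = genotypes.dosages[rows]
        called = (~np.isnan(sub)).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.nansum(sub, axis=0) / (2.0 * called)
        f = np.where(called > 0, f, np.nan)
        if (called == 0).any():
            logger.warning("population %s: %d variants with no called genotype",
                           pop, int((called == 0).sum()))
        freq_cols[pop] = f
        count_cols[pop] = 2.0 * called
    index = pd.Index(genotypes.variants["id"], name="id")
    return PopulationFrequencies(
        freq=pd.DataFrame(freq_cols, index=index),
        count=pd.DataFrame(count_cols, index=index),
    )


def hudson_fst(
    p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray
) -> tuple[np.ndarray, float]:
    """Hudson estimator of F_ST per variant plus the ratio-of-averages.

    Returns ``(per_variant, aggregate)``. Per-variant values are NaN where
    the denominator is zero or a frequency is missing; the aggregate is
    sum(num)/sum(den) over variants with both terms defined.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if (n1[np.isfinite(n1)] < 2).any() or (n2[np.isfinite(n2)] < 2).any():
        raise ValueError("allele counts must be >= 2 in both populations")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = np.isfinite(num) & np.isfinite(den) & (den > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_variant = np.where(ok, num / np.where(den > 0, den, np.nan), np.nan)
    aggregate = (
        float(num[ok].sum() / den[ok].sum()) if ok.any() else float("nan")
    )
    return per_variant, aggregate


def pairwise_fst_table(
    freqs: PopulationFrequencies, pairs: list[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Per-variant Hudson F_ST for each population pair (columns "A|B")."""
    pops = freqs.populations
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(pops) for b in pops[i + 1:]]
    out = {}
    for a, b in pairs:
        per, _ = hudson_fst(
            freqs.freq[a].to_numpy(), freqs.count[a].to_numpy(),
            freqs.freq[b].to_numpy(), freqs.count[b].to_numpy(),
        )
        out[f"{a}|{b}"] = per
    return pd.DataFrame(out, index=freqs.freq.index)


def fst_summary(fst_table: pd.DataFrame) -> pd.DataFrame:
    """Genome-wide mean and SD of per-variant F_ST for each pair.

    Computed across all variants with a defined F_ST; this supplies the
    E[F_ST^ij] and sd[F_ST^ij] standardization of the d-statistic.
    """
    summary = pd.DataFrame(
        {"mean": fst_table.mean(), "sd": fst_table.std(ddof=1)}
    )
    if (summary["sd"] <= 0).any():
        bad = summary.index[summary["sd"] <= 0].tolist()
        raise ValueError(f"zero F_ST standard deviation for pairs: {bad}")
    return summary


def branch_length(fst: np.ndarray) -> np.ndarray:
    """PBS branch length T = -log(1 - F_ST), with negatives clamped to 0."""
    f = np.clip(np.asarray(fst, dtype=float), 0.0, None)
    if (f[np.isfinite(f)] >= 1.0).any():
        logger.warning("F_ST = 1 encountered: infinite branch length")
    with np.errstate(divide="ignore"):
        return -np.log1p(-f)


def pbs(
    fst_focal_ref1: np.ndarray,
    fst_focal_ref2: np.ndarray,
    fst_ref1_ref2: np.ndarray,
) -> np.ndarray:
    """Population branch statistic of the focal population per variant.

    PBS = (T(focal,ref1) + T(focal,ref2) - T(ref1,ref2)) / 2 with
    T = -log(1 - F_ST). Missing inputs give missing output; negative PBS
    values are preserved.
    """
    t1 = branch_length(fst_focal_ref1)
    t2 = branch_length(fst_focal_ref2)
    t12 = branch_length(fst_ref1_ref2)
    return (t1 + t2 - t12) / 2.0


def polarized_d(
    freqs: PopulationFrequencies,
    fst_table: pd.DataFrame,
    summary: pd.DataFrame,
    focal_pop: str,
) -> np.ndarray:
    """Polarized d-statistic of ``focal_pop`` per variant.

    ``fst_table``/``summary`` come from :func:`pairwise_fst_table` and
    :func:`fst_summary`. Pairs with a missing frequency or F_ST at a
    variant are skipped for that variant.
    """
    others = [p for p in freqs.populations if p != focal_pop]
    if len(others) < 2:
        raise ValueError("need at least 2 non-focal populations")
    p_i = freqs.freq[focal_pop].to_numpy()
    total = np.zeros(len(freqs.freq))
    for pop in others:
        key = (
            f"{focal_pop}|{pop}" if f"{focal_pop}|{pop}" in fst_table.columns
            else f"{pop}|{focal_pop}"
        )
        if key not in fst_table.columns:
            raise KeyError(f"missing F_ST column for pair {focal_pop}/{pop}")
        mean, sd = float(summary.loc[key, "mean"]), float(summary.loc[key, "sd"])
        if sd <= 0:
            raise ValueError(f"zero F_ST SD for pair {key}")
        p_j = freqs.freq[pop].to_numpy()
        z = (fst_table[key].to_numpy() - mean) / sd
        sign = np.where(p_i >= p_j, 1.0, -1.0)
        term = sign * z
        total = total + np.where(np.isfinite(term), term, 0.0)
    return np.abs(total)


def ld_r2_window(
    genotypes: GenotypeDataset,
    lead_variant: str,
    window_bp: int = 100_000,
    subset: list[str] | None = None,
) -> pd.Series:
    """Squared Pearson correlation of dosages with a lead variant.

    Computed over ``subset`` samples (one population, typically) for every
    variant within ``window_bp`` of the lead, restricted to variants
    polymorphic in the subset. The lead itself is included (r^2 = 1).
    """
    j_lead = int(genotypes.variant_index([lead_variant])[0])
    rows = (
        genotypes.sample_subset(subset) if subset is not None
        else np.arange(genotypes.n_samples)
    )
    lead_pos = int(genotypes.variants["pos"].iloc[j_lead])
    lead_chrom = genotypes.variants["chrom"].iloc[j_lead]
    near = (
        (genotypes.variants["chrom"] == lead_chrom)
        & (genotypes.variants["pos"] - lead_pos).abs().le(window_bp)
    ).to_numpy()
    idx = np.flatnonzero(near)

    sub = genotypes.dosages[np.ix_(rows, idx)]
    x = genotypes.dosages[rows, j_lead]
    if np.nanstd(x) == 0:
        raise ValueError(f"lead variant {lead_variant} monomorphic in subset")

    out = {}
    for col, j in enumerate(idx):
        y = sub[:, col]
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 2 or np.std(y[ok]) == 0 or np.std(x[ok]) == 0:
            continue
        r = np.corrcoef(x[ok], y[ok])[0, 1]
        out[genotypes.variants["id"].iloc[j]] = r * r
    return pd.Series(out, name="r2")
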