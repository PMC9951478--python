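"""Cis-window association scanning and the hierarchical FDR.

The scan tests every pooled-MAF-passing variant within a fixed window of
each feature (gene TSS, or intron interval with distance 0 inside it)
against the normalized phenotype, adjusting for covariates. Two models
are available:

* ``ols`` — ordinary least squares with a Wald-style two-sided t test on
  the dosage coefficient, computed through the exact covariate
  residualization shortcut (identical to the full regression).
* ``lmm`` — a single-variance-component mixed model with a genetic
  relatedness matrix, solved by rotating into the GRM eigenbasis. The
  variance ratio is estimated once per feature on the covariates-only
  model by REML, then each variant is tested by generalized least
  squares at that ratio (exact per-variant REML behind a flag).

Multiple testing follows the hierarchical Benjamini-Hochberg procedure:
BH within each feature over its tested variants (single-corrected P'),
then BH across features on the per-feature minimum P' (double-corrected
P''). Features with P'' < alpha are significant; the genome-wide SNP
significance threshold is the minimum P' of the significant feature with
the largest P'', and every variant with P' at or below it is flagged.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CovariateMatrix, GenotypeDataset, PhenotypeMatrix

logger = logging.getLogger("tqtlkit")

ASSOC_COLUMNS = [
    "feature_id", "variant_id", "chrom", "pos", "ref", "alt", "maf",
    "beta", "se", "p",
]


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------

def compute_grm(genotypes: GenotypeDataset) -> np.ndarray:
    """Genetic relatedness matrix XX'/M over standardized dosage columns.

    Columns are standardized to mean 0 and variance 1 (population
    variance); monomorphic variants are skipped. The diagonal mean is 1
    exactly under this standardization.
    """
    dos = _imputed_dosages(genotypes)
    mu = dos.mean(axis=0)
    sd = dos.std(axis=0)
    poly = sd > 0
    if not poly.any():
        raise ValueError("no polymorphic variants for the GRM")
    x = (dos[:, poly] - mu[poly]) / sd[poly]
    return x @ x.T / poly.sum()


def _imputed_dosages(genotypes: GenotypeDataset) -> np.ndarray:
    """Dosage matrix with missing values mean-imputed per variant."""
    dos = genotypes.dosages.copy()
    if np.isnan(dos).any():
        col_mean = np.nanmean(dos, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(dos))
        dos[nan_r, nan_c] = col_mean[nan_c]
    return dos


# ---------------------------------------------------------------------------
# Window lookup
# ---------------------------------------------------------------------------

def cis_window_variants(
    genotypes: GenotypeDataset, feature: pd.Series, window_bp: int
) -> np.ndarray:
    """Indices of variants within ``window_bp`` of a feature.

    Genes: distance from the TSS. Introns: distance from the half-open
    interval, zero for variants inside it. Chromosomes must match.
    """
    pos = genotypes.variants["pos"].to_numpy()
    same_chrom = (genotypes.variants["chrom"] == feature["chrom"]).to_numpy()
    if feature["kind"] == "gene":
        dist = np.abs(pos - int(feature["tss"]))
    else:
        start1 = int(feature["start"]) + 1          # first base, 1-based
        end1 = int(feature["end"])                  # last base, 1-based
        dist = np.where(
            pos < start1, start1 - pos, np.where(pos > end1, pos - end1, 0)
        )
    return np.flatnonzero(same_chrom & (dist <= window_bp))


# ---------------------------------------------------------------------------
# Mixed-model machinery
# ---------------------------------------------------------------------------

def _reml_neg_loglik(
    log_lam: float, d: np.ndarray, yr: np.ndarray, cr: np.ndarray
) -> float:
    lam = np.exp(log_lam)
    v = lam * d + 1.0
    w = 1.0 / v
    cw = cr * w[:, None]
    xtx = cr.T @ cw
    xty = cw.T @ yr
    beta = np.linalg.solve(xtx, xty)
    resid = yr - cr @ beta
    rss = float(resid @ (w * resid))
    n, p = cr.shape
    sigma2 = rss / (n - p)
    sign, logdet = np.linalg.slogdet(xtx)
    return 0.5 * (np.log(v).sum() + logdet + (n - p) * np.log(sigma2))


def _fit_variance_ratio(
    d: np.ndarray, yr: np.ndarray, cr: np.ndarray
) -> float:
    """REML estimate of the variance ratio sigma_g^2 / sigma_e^2."""
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(-10.0, 10.0), args=(d, yr, cr),
        method="bounded", options={"xatol": 1e-6},
    )
    return float(np.exp(res.x))


def _wls_t_test(
    y: np.ndarray, design: np.ndarray, w: np.ndarray
) -> tuple[float, float, float]:
    """Weighted LS; returns (beta, se, p) for the LAST design column."""
    dw = design * w[:, None]
    xtx = design.T @ dw
    xty = dw.T @ y
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ xty
    resid = y - design @ beta
    n, p = design.shape
    sigma2 = float(resid @ (w * resid)) / (n - p)
    se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
    t = beta[-1] / se
    pval = 2.0 * stats.t.sf(abs(t), n - p)
    return float(beta[-1]), se, float(pval)


# ---------------------------------------------------------------------------
# The scan
# ---------------------------------------------------------------------------

def cis_scan(
    genotypes: GenotypeDataset,
    phenotypes: PhenotypeMatrix,
    covariates: CovariateMatrix | None = None,
    window_bp: int = 100_000,
    maf_min: float = 0.05,
    model: str = "ols",
    grm: np.ndarray | None = None,
    exact_per_variant_reml: bool = False,
) -> pd.DataFrame:
    """Scan every feature against its cis-window variants.

    Returns one row per tested feature-variant pair with columns
    ``feature_id, variant_id, chrom, pos, ref, alt, maf, beta, se, p``.
    Variants need pooled MAF strictly above ``maf_min``; dosages are
    mean-imputed where missing, and variants constant after imputation
    are skipped. Features whose window holds no testable variant are
    skipped with a log entry.
    """
    if model not in ("ols", "lmm"):
        raise ValueError(f"model must be 'ols' or 'lmm', got {model!r}")
    if window_bp <= 0 or maf_min < 0:
        raise ValueError("window and MAF thresholds must be positive")
    if phenotypes.sample_ids != list(genotypes.sample_ids):
        raise ValueError("phenotype sample order does not match genotypes")

    n = genotypes.n_samples
    dos = _imputed_dosages(genotypes)
    maf = genotypes.maf
    testable = (maf > maf_min) & (dos.std(axis=0) > 0)

    cov = (
        covariates.aligned(genotypes.sample_ids)
        if covariates is not None else np.empty((n, 0))
    )
    design_c = np.column_stack([np.ones(n), cov])
    p_cov = design_c.shape[1]

    if model == "lmm":
        if grm is None:
            grm = compute_grm(genotypes)
        d_eig, u_eig = np.linalg.eigh(grm)
        d_eig = np.clip(d_eig, 0.0, None)
        rot = u_eig.T
        cr = rot @ design_c
        xr_all = rot @ dos
    else:
        # exact OLS through residualization on the covariate design
        q, _ = np.linalg.qr(design_c)
        y_all = phenotypes.values.to_numpy(dtype=float)
        y_res = y_all.T - q @ (q.T @ y_all.T)         # samples x features
        x_res = dos - q @ (q.T @ dos)
        sx2 = (x_res ** 2).sum(axis=0)

    var_tab = genotypes.variants
    rows: list[tuple] = []
    for f_idx, feature in phenotypes.features.iterrows():
        idx = cis_window_variants(genotypes, feature, window_bp)
        idx = idx[testable[idx]]
        if idx.size == 0:
            logger.info("feature %s: no testable variant in cis window, skipped",
                        feature["id"])
            continue
        fid = feature["id"]
        if model == "ols":
            yv = y_res[:, f_idx]
            syy = float(yv @ yv)
            xs2 = sx2[idx]
            xty = x_res[:, idx].T @ yv
            beta = xty / xs2
            rss = np.maximum(syy - beta ** 2 * xs2, 0.0)
            df = n - p_cov - 1
            sigma2 = rss / df
            se = np.sqrt(sigma2 / xs2)
            with np.errstate(divide="ignore", invalid="ignore"):
                tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
            pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
            for k, j in enumerate(idx):
                v = var_tab.iloc[j]
                rows.append((fid, v["id"], v["chrom"], v["pos"], v["ref"],
                             v["alt"], maf[j], beta[k], se[k], pvals[k]))
        else:
            yr = rot @ phenotypes.values.to_numpy(dtype=float)[f_idx]
            lam = _fit_variance_ratio(d_eig, yr, cr)
            w = 1.0 / (lam * d_eig + 1.0)
            for j in idx:
                design = np.column_stack([cr, xr_all[:, j]])
                if exact_per_variant_reml:
                    lam_j = _fit_variance_ratio(d_eig, yr, design)
                    w_j = 1.0 / (lam_j * d_eig + 1.0)
                else:
                    w_j = w
                beta, se, pval = _wls_t_test(yr, design, w_j)
                v = var_tab.iloc[j]
                rows.append((fid, v["id"], v["chrom"], v["pos"], v["ref"],
                             v["alt"], maf[j], beta, se, pval))
    return pd.DataFrame(rows, columns=ASSOC_COLUMNS)


# ---------------------------------------------------------------------------
# Hierarchical FDR
# ---------------------------------------------------------------------------

def hierarchical_fdr(
    records: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-level Benjamini-Hochberg over a cis-scan result.

    Returns ``(feature_table, association_table)``. The feature table has
    ``feature_id, min_P_prime, P_double_prime, significant,
    snp_threshold``; the association table is the input plus ``P_prime``
    and ``significant``. The SNP threshold is the minimum P' of the
    significant feature with the largest P''; variants with
    P' <= threshold are flagged (the lead variant of the borderline
    feature is therefore always included).
    """
    if records.empty:
        raise ValueError("no association records")
    recs = records.copy()
    recs["P_prime"] = recs.groupby("feature_id")["p"].transform(
        lambda p: multipletests(p, method="fdr_bh")[1]
    )
    feat = (
        recs.groupby("feature_id")["P_prime"].min().rename("min_P_prime")
        .reset_index()
    )
    feat["P_double_prime"] = multipletests(
        feat["min_P_prime"], method="fdr_bh"
    )[1]
    feat["significant"] = feat["P_double_prime"] < alpha

    if feat["significant"].any():
        sig = feat.loc[feat["significant"]]
        borderline = sig.loc[sig["P_double_prime"].idxmax()]
        threshold = float(borderline["min_P_prime"])
    else:
        threshold = np.nan
    feat["snp_threshold"] = threshold
    recs["significant"] = (
        recs["P_prime"] <= threshold if np.isfinite(threshold)
        else False
    )
    return feat, recs


# ---------------------------------------------------------------------------
# Conditional scan
# ---------------------------------------------------------------------------

def conditional_scan(
    genotypes: GenotypeDataset,
    phenotypes: PhenotypeMatrix,
    covariates: CovariateMatrix | None,
    conditioning_variants: Mapping[str, Sequence[str]],
    original_threshold: float,
    **scan_kwargs,
) -> tuple[pd.Series, pd.DataFrame]:
    """Re-scan after residualizing phenotypes on conditioning dosages.

    ``conditioning_variants`` maps feature id -> variant ids to condition
    on (absent variants are dropped with a log entry; variants collinear
    with the covariates are dropped with a warning). Each feature's
    phenotype is replaced by the residuals of a regression on intercept,
    covariates, and its conditioning dosages, and the cis scan is re-run.
    A feature is independent iff any variant attains within-feature
    BH-adjusted P' at or below ``original_threshold``.

    Returns ``(independent_flags, conditional_associations)``.
    """
    n = genotypes.n_samples
    dos = _imputed_dosages(genotypes)
    cov = (
        covariates.aligned(genotypes.sample_ids)
        if covariates is not None else np.empty((n, 0))
    )
    base = np.column_stack([np.ones(n), cov])
    q_base, _ = np.linalg.qr(base)

    values = phenotypes.values.copy()
    id_index = pd.Index(genotypes.variants["id"])
    for fid in values.index:
        wanted = list(conditioning_variants.get(fid, []))
        if not wanted:
            continue
        found = [v for v in wanted if v in id_index]
        if len(found) < len(wanted):
            logger.info("feature %s: %d conditioning variants absent, dropped",
                        fid, len(wanted) - len(found))
        if not found:
            continue
        g = dos[:, id_index.get_indexer(found)]
        g_res = g - q_base @ (q_base.T @ g)
        keep = np.linalg.norm(g_res, axis=0) > 1e-8 * np.sqrt(n)
        if not keep.all():
            logger.warning("feature %s: conditioning variant collinear with "
                           "covariates, dropped", fid)
        g = g[:, keep]
        if g.shape[1] == 0:
            continue
        design = np.column_stack([base, g])
        y = values.loc[fid].to_numpy(dtype=float)
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        values.loc[fid] = y - design @ coef

    resid_pm = PhenotypeMatrix(values=values, features=phenotypes.features.copy(),
                               norm_state=phenotypes.norm_state)
    recs = cis_scan(genotypes, resid_pm, covariates, **scan_kwargs)
    if recs.empty:
        flags = pd.Series(False, index=phenotypes.values.index)
        return flags, recs
    recs["P_prime"] = recs.groupby("feature_id")["p"].transform(
        lambda p: multipletests(p, method="fdr_bh")[1]
    )
    best = recs.groupby("feature_id")["P_prime"].min()
    flags = (best <= original_threshold).reindex(
        phenotypes.values.index, fill_value=False
    )
    flags.name = "independent"
    return flags, recs
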