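"""Synthetic multi-population QTL data with known truth.

The generator emulates the statistical structure the analysis pipeline
assumes: several populations differentiated under the Balding-Nichols
model (per-population allele frequencies Beta-distributed around an
ancestral frequency with drift parameter F, so pairwise Hudson F_ST has a
known target), additive cis-acting genetic effects on continuous
expression-like phenotypes, intron-cluster junction counts whose one
junction's proportion shifts on the logit scale with genotype, and
nuisance covariates including latent factors with genome-wide loadings.

Everything is driven by a single integer seed; identical configurations
produce byte-identical outputs. One synthetic chromosome is used, with
variants at fixed spacing so cis windows have predictable occupancy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io_formats import (
    FEATURE_COLUMNS,
    VARIANT_COLUMNS,
    CovariateMatrix,
    GenotypeDataset,
    PhenotypeMatrix,
    write_genotypes_vcf,
    write_phenotype_bed,
    write_table,
)

logger = logging.getLogger("tqtlkit")

_CHROM = "chrS"

# rng stream tags so that each operation draws from an independent,
# reproducible stream derived from the one config seed
_TAG_GENO, _TAG_COV, _TAG_EXPR, _TAG_SPLICE = 11, 13, 17, 19


@dataclass
class SimConfig:
    """Configuration of one synthetic study.

    Defaults mirror a small multi-population whole-blood cohort: 162
    diploid samples in 3 populations with modest differentiation
    (F = 0.05 per population), a 100 kb cis window, and per-allele effects
    around half a phenotypic standard deviation for causal features.
    """

    n_pops: int = 3
    samples_per_pop: int = 54
    n_variants: int = 2000
    n_genes: int = 200
    introns_per_cluster: int = 3
    n_clusters: int = 40
    fst_targets: tuple[float, ...] | None = None
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    cis_window_bp: int = 100_000
    variant_spacing_bp: int = 1000
    effect_size_sd: float = 0.5
    frac_causal: float = 0.3
    noise_sd: float = 1.0
    latent_factors: int = 2
    mean_cluster_reads: float = 150.0
    splicing_overdispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pops", "samples_per_pop", "n_variants", "n_genes",
                     "introns_per_cluster", "n_clusters", "cis_window_bp",
                     "variant_spacing_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.samples_per_pop < 2:
            raise ValueError("samples_per_pop must be >= 2 for frequency estimation")
        if self.introns_per_cluster < 2:
            raise ValueError("clusters need at least 2 junctions")
        if self.fst_targets is None:
            self.fst_targets = (0.05,) * self.n_pops
        if len(self.fst_targets) != self.n_pops:
            raise ValueError("fst_targets must have one entry per population")
        for f in self.fst_targets:
            if not (0.0 <= f < 1.0):
                raise ValueError(f"drift parameter F must be in [0, 1), got {f}")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("ancestral_freq_range must be within (0, 1)")
        if not (0.0 <= self.frac_causal <= 1.0):
            raise ValueError("frac_causal must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.n_pops * self.samples_per_pop

    @property
    def chrom_length(self) -> int:
        return (self.n_variants + 1) * self.variant_spacing_bp

    @property
    def pop_labels(self) -> list[str]:
        return [f"pop{i + 1}" for i in range(self.n_pops)]


class ExpressionSimulation(NamedTuple):
    phenotypes: PhenotypeMatrix          # continuous, quantile-normalizable
    truth: pd.DataFrame                  # one row per gene
    counts: pd.DataFrame                 # Poisson read-count layer (filters)
    tpm: pd.DataFrame                    # abundance layer (filters)


class SplicingSimulation(NamedTuple):
    phenotypes: PhenotypeMatrix          # JPC = junction / cluster total
    truth: pd.DataFrame                  # one row per intron
    junction_counts: pd.DataFrame
    cluster_totals: pd.DataFrame         # samples x clusters


class CovariateSimulation(NamedTuple):
    covariates: CovariateMatrix
    gene_loadings: pd.DataFrame          # covariate x gene effect sizes


@dataclass
class SimulatedDataset:
    config: SimConfig
    genotypes: GenotypeDataset
    population_freqs: pd.DataFrame       # true Balding-Nichols frequencies
    covariates: CovariateMatrix
    expression: ExpressionSimulation
    splicing: SplicingSimulation

    @property
    def truth(self) -> pd.DataFrame:
        return pd.concat(
            [self.expression.truth, self.splicing.truth], ignore_index=True
        )


def _sample_ids(config: SimConfig) -> list[str]:
    return [f"s{i:04d}" for i in range(config.n_samples)]


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Draw Balding-Nichols genotypes for all populations.

    Ancestral frequencies are uniform on ``ancestral_freq_range``; each
    population's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) around the
    ancestral p (or exactly p when F = 0), and diploid dosages are
    Binomial(2, p_pop). Returns the dataset and the frame of true
    per-population frequencies (variants x populations).
    """
    rng = np.random.default_rng([_TAG_GENO, config.seed])
    lo, hi = config.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=config.n_variants)

    pop_freqs = np.empty((config.n_variants, config.n_pops))
    for k, f in enumerate(config.fst_targets):
        if f == 0.0:
            pop_freqs[:, k] = p_anc
        else:
            scale = (1.0 - f) / f
            pop_freqs[:, k] = rng.beta(p_anc * scale, (1.0 - p_anc) * scale)

    dosages = np.empty((config.n_samples, config.n_variants))
    populations = []
    for k in range(config.n_pops):
        rows = slice(k * config.samples_per_pop, (k + 1) * config.samples_per_pop)
        dosages[rows] = rng.binomial(
            2, pop_freqs[:, k], size=(config.samples_per_pop, config.n_variants)
        )
        populations.extend([config.pop_labels[k]] * config.samples_per_pop)

    positions = (np.arange(config.n_variants) + 1) * config.variant_spacing_bp
    variants = pd.DataFrame(
        {
            "chrom": _CHROM,
            "pos": positions,
            "id": [f"var{j:05d}" for j in range(config.n_variants)],
            "ref": "A",
            "alt": "G",
        },
        columns=VARIANT_COLUMNS,
    )
    variants["monomorphic"] = (dosages == dosages[0]).all(axis=0)

    dataset = GenotypeDataset(
        dosages=dosages,
        variants=variants,
        sample_ids=_sample_ids(config),
        populations=pd.Series(populations, index=_sample_ids(config)),
    )
    freq_frame = pd.DataFrame(
        pop_freqs, index=variants["id"], columns=config.pop_labels
    )
    return dataset, freq_frame


def simulate_covariates(config: SimConfig) -> CovariateSimulation:
    """Generate nuisance covariates and their loadings on gene phenotypes.

    One binary covariate (sex analogue), one continuous covariate (age
    analogue), and ``latent_factors`` standard-normal latent factors. The
    returned loadings (covariate x gene) are what the expression simulator
    adds to each gene; latent factors load on every gene so a
    principal-component surrogate can recover them.
    """
    rng = np.random.default_rng([_TAG_COV, config.seed])
    n = config.n_samples
    cols = {
        "sex": rng.integers(0, 2, size=n).astype(float),
        "age": rng.normal(40.0, 10.0, size=n),
    }
    for k in range(config.latent_factors):
        cols[f"factor{k + 1}"] = rng.normal(0.0, 1.0, size=n)
    data = pd.DataFrame(cols, index=_sample_ids(config))

    loadings = np.zeros((len(cols), config.n_genes))
    loadings[0] = rng.normal(0.0, 0.1, size=config.n_genes)          # sex
    loadings[1] = rng.normal(0.0, 0.01, size=config.n_genes)         # age
    for k in range(config.latent_factors):
        loadings[2 + k] = rng.normal(0.0, 0.5, size=config.n_genes)  # latent
    gene_ids = [f"gene{g:04d}" for g in range(config.n_genes)]
    return CovariateSimulation(
        covariates=CovariateMatrix(data),
        gene_loadings=pd.DataFrame(loadings, index=list(cols), columns=gene_ids),
    )


def _pick_causal_variant(
    genotypes: GenotypeDataset,
    center: int,
    window: int,
    rng: np.random.Generator,
    maf_min: float = 0.05,
) -> int | None:
    """Index of a random common variant within ``window`` of ``center``."""
    pos = genotypes.variants["pos"].to_numpy()
    in_window = np.abs(pos - center) <= window
    common = genotypes.maf > maf_min
    candidates = np.flatnonzero(in_window & common)
    if candidates.size == 0:
        return None
    return int(rng.choice(candidates))


def simulate_expression_phenotypes(
    genotypes: GenotypeDataset,
    config: SimConfig,
    covariates: CovariateSimulation | None = None,
    effect_size: float | None = None,
) -> ExpressionSimulation:
    """Simulate continuous expression phenotypes with additive cis effects.

    Each gene receives a TSS on the synthetic chromosome; a fraction
    ``frac_causal`` of genes get one causal common variant inside the cis
    window, with per-allele effect drawn N(0, effect_size_sd) unless
    ``effect_size`` fixes it. Phenotype = effect x dosage + covariate
    contributions + N(0, noise_sd). A Poisson read-count layer (and a TPM
    layer) is emitted so the expression feature filters can be exercised.
    """
    rng = np.random.default_rng([_TAG_EXPR, config.seed])
    if covariates is None:
        covariates = simulate_covariates(config)
    n = config.n_samples
    gene_ids = list(covariates.gene_loadings.columns)
    tss = np.linspace(
        config.variant_spacing_bp, config.chrom_length - config.variant_spacing_bp,
        config.n_genes,
    ).astype(int)

    cov_values = covariates.covariates.data.to_numpy()           # n x c
    cov_contrib = cov_values @ covariates.gene_loadings.to_numpy()  # n x G

    is_causal = rng.random(config.n_genes) < config.frac_causal
    values = np.empty((config.n_genes, n))
    truth_rows = []
    for g in range(config.n_genes):
        causal_id, effect = None, 0.0
        if is_causal[g]:
            j = _pick_causal_variant(genotypes, tss[g], config.cis_window_bp, rng)
            if j is None:
                logger.warning(
                    "gene %s: no common variant in cis window, made non-causal",
                    gene_ids[g],
                )
            else:
                causal_id = genotypes.variants["id"].iloc[j]
                effect = (
                    effect_size if effect_size is not None
                    else rng.normal(0.0, config.effect_size_sd)
                )
        genetic = (
            effect * np.nan_to_num(genotypes.dosages[:, genotypes.variant_index([causal_id])[0]])
            if causal_id is not None else 0.0
        )
        values[g] = genetic + cov_contrib[:, g] + rng.normal(0, config.noise_sd, n)
        truth_rows.append((gene_ids[g], "gene", causal_id, effect))

    features = pd.DataFrame(
        {
            "id": gene_ids,
            "kind": "gene",
            "chrom": _CHROM,
            "tss": tss,
            "start": tss - 1,
            "end": tss,
            "cluster_id": "",
        },
        columns=FEATURE_COLUMNS,
    )
    value_df = pd.DataFrame(values, index=pd.Index(gene_ids, name="id"),
                            columns=_sample_ids(config))
    truth = pd.DataFrame(
        truth_rows, columns=["feature_id", "kind", "causal_variant_id", "true_effect"]
    )

    # read-count layer: counts ~ Poisson(50 * exp(z)) with z the standardized
    # phenotype, TPM proportional to the Poisson mean
    z = (values - values.mean(axis=1, keepdims=True)) / np.maximum(
        values.std(axis=1, keepdims=True), 1e-12
    )
    lam = 50.0 * np.exp(z)
    counts = pd.DataFrame(rng.poisson(lam), index=value_df.index,
                          columns=value_df.columns)
    tpm = pd.DataFrame(lam / lam.sum(axis=0, keepdims=True) * 1e6,
                       index=value_df.index, columns=value_df.columns)

    return ExpressionSimulation(
        phenotypes=PhenotypeMatrix(values=value_df, features=features),
        truth=truth, counts=counts, tpm=tpm,
    )


def simulate_splicing_phenotypes(
    genotypes: GenotypeDataset,
    config: SimConfig,
    effect_size: float | None = None,
) -> SplicingSimulation:
    """Simulate intron-cluster junction counts and JPC phenotypes.

    Per cluster and sample, the total read count is Poisson with mean
    ``mean_cluster_reads`` and junction counts are multinomial around
    Dirichlet-drawn baseline proportions. For causal clusters the first
    junction's proportion shifts on the logit scale by effect x dosage of
    one common cis variant. JPC (junction proportion per cluster) is the
    junction count divided by the cluster total. With
    ``splicing_overdispersion > 0`` proportions are redrawn per sample from
    a Dirichlet around the baseline (Dirichlet-multinomial counts).
    """
    rng = np.random.default_rng([_TAG_SPLICE, config.seed])
    if config.introns_per_cluster < 2:
        raise ValueError("clusters need at least 2 junctions")
    n, k = config.n_samples, config.introns_per_cluster
    centers = np.linspace(
        config.variant_spacing_bp * 2, config.chrom_length - 2 * config.variant_spacing_bp,
        config.n_clusters,
    ).astype(int)

    is_causal = rng.random(config.n_clusters) < config.frac_causal
    intron_ids, feat_rows, truth_rows = [], [], []
    jpc_rows, count_rows = [], []
    totals = np.empty((n, config.n_clusters), dtype=int)

    for c in range(config.n_clusters):
        cluster = f"clu{c + 1}"
        base = rng.dirichlet(np.full(k, 5.0))
        causal_id, effect = None, 0.0
        dos = np.zeros(n)
        if is_causal[c]:
            j = _pick_causal_variant(genotypes, centers[c], config.cis_window_bp, rng)
            if j is None:
                logger.warning("cluster %s: no common cis variant, made non-causal",
                               cluster)
            else:
                causal_id = genotypes.variants["id"].iloc[j]
                effect = (
                    effect_size if effect_size is not None
                    else rng.normal(0.0, config.effect_size_sd)
                )
                dos = np.nan_to_num(
                    genotypes.dosages[:, genotypes.variant_index([causal_id])[0]]
                )
        # per-sample proportions: logit shift on junction 0
        logits = np.log(np.tile(base, (n, 1)))
        logits[:, 0] += effect * dos
        props = np.exp(logits)
        props /= props.sum(axis=1, keepdims=True)
        if config.splicing_overdispersion > 0:
            conc = 1.0 / config.splicing_overdispersion
            props = np.vstack([rng.dirichlet(p * conc) for p in props])

        tot = rng.poisson(config.mean_cluster_reads, size=n)
        totals[:, c] = tot
        counts = np.vstack(
            [rng.multinomial(t, p) if t > 0 else np.zeros(k, dtype=int)
             for t, p in zip(tot, props)]
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            jpc = np.where(tot[:, None] > 0, counts / np.maximum(tot[:, None], 1), 0.0)

        for m in range(k):
            iid = f"{cluster}:intron{m + 1}"
            intron_ids.append(iid)
            start = centers[c] + m * 100
            feat_rows.append((iid, "intron", _CHROM, np.nan, start, start + 80,
                              cluster))
            jpc_rows.append(jpc[:, m])
            count_rows.append(counts[:, m])
            truth_rows.append(
                (iid, "intron", causal_id if m == 0 else None,
                 effect if m == 0 else 0.0)
            )

    samples = _sample_ids(config)
    features = pd.DataFrame(feat_rows, columns=FEATURE_COLUMNS)
    value_df = pd.DataFrame(np.vstack(jpc_rows),
                            index=pd.Index(intron_ids, name="id"), columns=samples)
    counts_df = pd.DataFrame(np.vstack(count_rows), index=value_df.index,
                             columns=samples)
    totals_df = pd.DataFrame(totals, index=samples,
                             columns=[f"clu{c + 1}" for c in range(config.n_clusters)])
    truth = pd.DataFrame(
        truth_rows, columns=["feature_id", "kind", "causal_variant_id", "true_effect"]
    )
    return SplicingSimulation(
        phenotypes=PhenotypeMatrix(values=value_df, features=features),
        truth=truth, junction_counts=counts_df, cluster_totals=totals_df,
    )


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the whole generator: genotypes, covariates, expression, splicing."""
    genotypes, pop_freqs = simulate_genotypes(config)
    cov = simulate_covariates(config)
    expr = simulate_expression_phenotypes(genotypes, config, covariates=cov)
    splice = simulate_splicing_phenotypes(genotypes, config)
    return SimulatedDataset(
        config=config, genotypes=genotypes, population_freqs=pop_freqs,
        covariates=cov.covariates, expression=expr, splicing=splice,
    )


def write_dataset(
    genotypes: GenotypeDataset,
    phenotypes: dict[str, PhenotypeMatrix],
    covariates: CovariateMatrix,
    truth: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write one simulation to disk (VCF, phenotype BEDs, TSV tables).

    ``phenotypes`` maps a short name (e.g. ``"expression"``) to a matrix;
    each becomes ``<name>.bed``. Read-back through io_formats reproduces
    the in-memory values exactly (floats are written with ``repr``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["vcf"] = write_genotypes_vcf(genotypes, out / "genotypes.vcf")
    pops = pd.DataFrame({"population": genotypes.populations})
    paths["populations"] = write_table(pops, out / "populations.tsv")
    for name, pm in phenotypes.items():
        paths[name] = write_phenotype_bed(pm, out / f"{name}.bed")
    paths["covariates"] = write_table(covariates.data, out / "covariates.tsv")
    paths["truth"] = write_table(truth, out / "truth.tsv", index=False)
    return paths
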