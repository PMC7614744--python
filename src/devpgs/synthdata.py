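"""Synthetic cohort generator for the developmental-PGS pipeline.

Generates every input the analysis needs with the statistical structure it
assumes — LD-blocked genotypes in Hardy-Weinberg equilibrium, eight disorder
GWAS whose genetic covariance follows a planted three-factor structure, a
six-region developmental expression atlas with planted prenatal-peak and
postnatal-peak genes, a non-overlapping gene map, and twelve correlated
psychopathology scales driven by a partitioned genetic score plus site, sex
and age covariates.  Alongside each dataset a :class:`TruthRecord` stores
the planted quantities (true per-SNP effects, factor effects, gene timing
classes, true liability) so recovery tests never need to re-simulate.

Design notes
------------
* Genotypes are drawn by thresholding AR(rho) latent Gaussian haplotypes at
  the Hardy-Weinberg quantile of each SNP's allele frequency: marginal MAF
  is exact, genotypes are in HWE by construction, and within-block LD decays
  geometrically with SNP distance.  Blocks are independent.
* GWAS z-scores are simulated analytically, ``z = sqrt(n) * (R b) +
  R^(1/2) e`` with ``R`` the within-block panel correlation and ``b`` the
  true standardized effects: the noise is LD-correlated exactly as in a
  real single-cohort GWAS, and the LD-score regression expectation
  ``E[chi2_j] = 1 + n h2 l_j / M`` holds exactly (noise variance 1).
* Phenotype scales are continuous and reported as T-scores (mean 50, sd 10)
  with the clinical cutoff at Total >= 64.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    CLINICAL_CUTOFF,
    DISORDERS,
    FACTORS,
    SCALES,
    SimulationConfig,
)
from .genio import MISSING, GenotypePanel, write_plink, write_sumstats

# rng stream codes per operation, so each dataset is reproducible on its own
_RNG_GENO, _RNG_SUMSTATS, _RNG_ATLAS, _RNG_PHENO, _RNG_GENEMAP = range(5)

# unambiguous (non strand-complementary) allele pairs
_ALLELE_PAIRS = [
    ("A", "G"),
    ("A", "C"),
    ("T", "G"),
    ("T", "C"),
    ("G", "A"),
    ("C", "A"),
    ("G", "T"),
    ("C", "T"),
]

TIMING_CLASSES = ("prenatal", "postnatal", "continuous")


def gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:06d}" for i in range(n)]


@dataclass
class TruthRecord:
    """Planted ground truth accompanying a simulated study."""

    config: SimulationConfig
    true_effects: np.ndarray | None = None  # (M, n_disorders) standardized betas
    factor_effects: np.ndarray | None = None  # (M, 3) per-SNP factor effects
    gene_classes: pd.DataFrame | None = None  # region, gene, class
    gene_map: pd.DataFrame | None = None  # gene_id, chrom, start, end, strand
    liability: np.ndarray | None = None  # per-individual true genetic score
    causal_snps: list[str] = field(default_factory=list)

    def true_genetic_covariance(self) -> np.ndarray:
        """Population genetic covariance implied by the planted model:
        ``sqrt(h2_d h2_e) * (Lambda Phi Lambda')_de`` off the diagonal and
        ``h2_d`` on it."""
        cfg = self.config
        lam, phi = cfg.factor_loadings, cfg.factor_corr
        shared = lam @ phi @ lam.T
        h = np.sqrt(cfg.h2_per_disorder)
        s = np.outer(h, h) * shared
        np.fill_diagonal(s, cfg.h2_per_disorder)
        return s


@dataclass
class SimulatedStudy:
    panel: GenotypePanel
    sumstats: dict[str, pd.DataFrame]
    atlas: "object"
    gene_map: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: TruthRecord


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(config: SimulationConfig) -> GenotypePanel:
    """LD-blocked dosage panel with exact marginal MAF and HWE genotypes.

    Two independent latent AR(``ld_rho``) Gaussian haplotypes per individual
    are thresholded at ``Phi^-1(maf_j)``; the dosage is the number of
    sub-threshold haplotypes, so each SNP is Binomial(2, maf_j).
    """
    rng = np.random.default_rng([config.seed, _RNG_GENO])
    n, m, bs = config.n_individuals, config.n_snps, config.ld_block_size
    rho_cfg = np.atleast_1d(np.asarray(config.ld_rho, dtype=float))
    n_blocks = (m + bs - 1) // bs
    if rho_cfg.size == 2:
        block_rho = rng.uniform(rho_cfg[0], rho_cfg[1], n_blocks)
    else:
        block_rho = np.full(n_blocks, rho_cfg[0])
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    thresholds = stats.norm.ppf(mafs)

    dosages = np.empty((n, m), dtype=np.int8)
    start = 0
    while start < m:
        stop = min(start + bs, m)
        width = stop - start
        rho = float(block_rho[start // bs])
        eps = rng.standard_normal((2 * n, width))
        latent = np.empty_like(eps)
        latent[:, 0] = eps[:, 0]
        scale = np.sqrt(1 - rho * rho)
        for j in range(1, width):
            latent[:, j] = rho * latent[:, j - 1] + scale * eps[:, j]
        alleles = (latent < thresholds[start:stop]).astype(np.int8)
        dosages[:, start:stop] = alleles[:n] + alleles[n:]
        start = stop

    if config.missing_rate > 0:
        miss = rng.random((n, m)) < config.missing_rate
        dosages[miss] = MISSING

    pairs = [_ALLELE_PAIRS[k] for k in rng.integers(0, len(_ALLELE_PAIRS), size=m)]
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": (np.arange(m) + 1) * config.snp_spacing_bp,
            "id": [f"snp{j + 1:07d}" for j in range(m)],
            "a1": [p[0] for p in pairs],
            "a2": [p[1] for p in pairs],
        }
    )
    samples = np.array([f"IND{i + 1:06d}" for i in range(n)], dtype=object)
    return GenotypePanel(samples, variants, dosages)


# ---------------------------------------------------------------------------
# multi-trait GWAS summary statistics
# ---------------------------------------------------------------------------


def _block_correlations(panel: GenotypePanel, block_size: int) -> list[np.ndarray]:
    x = panel.standardized()
    n = panel.n_samples
    out = []
    for start in range(0, panel.n_variants, block_size):
        xb = x[:, start : start + block_size]
        out.append(xb.T @ xb / n)
    return out


def simulate_multitrait_sumstats(
    config: SimulationConfig,
    panel: GenotypePanel,
    truth: TruthRecord | None = None,
) -> tuple[dict[str, pd.DataFrame], TruthRecord]:
    """Eight-disorder GWAS summary statistics with a planted factor model.

    Per-SNP true standardized effects are ``b_d = sqrt(h2_d) * (Lambda eta +
    u_d)`` with factor effects ``eta ~ N(0, Phi/M)`` and uniquenesses
    ``u_d ~ N(0, (1 - communality_d)/M)``, so ``Var(b_d) = h2_d / M`` and the
    cross-disorder covariance of true effects is the h2-scaled
    ``Lambda Phi Lambda'``.  Z-scores add LD smearing through the panel's
    within-block correlations plus unit Gaussian noise.
    """
    cfg = config
    if cfg.factor_loadings.shape[0] != cfg.n_disorders:
        raise ValueError("factor_loadings rows must equal n_disorders")
    comm = cfg.communalities
    if np.any(comm > 1 + 1e-9):
        raise ValueError("factor loadings imply per-disorder genetic variance > 1")

    rng = np.random.default_rng([cfg.seed, _RNG_SUMSTATS])
    m = panel.n_variants
    k = cfg.n_disorders
    lam, phi = cfg.factor_loadings, cfg.factor_corr

    eta = rng.standard_normal((m, lam.shape[1])) @ np.linalg.cholesky(phi).T
    eta /= np.sqrt(m)
    uniq = rng.standard_normal((m, k)) * np.sqrt(np.clip(1 - comm, 0, None) / m)
    b = (eta @ lam.T + uniq) * np.sqrt(cfg.h2_per_disorder)

    # LD smearing of signal (R b) and LD-correlated noise (R^(1/2) e)
    smeared = np.empty_like(b)
    noise = rng.standard_normal((m, k))
    blocks = _block_correlations(panel, cfg.ld_block_size)
    start = 0
    for r in blocks:
        stop = start + r.shape[0]
        smeared[start:stop] = r @ b[start:stop]
        w_eig, v_eig = np.linalg.eigh(r)
        root = (v_eig * np.sqrt(np.clip(w_eig, 0.0, None))) @ v_eig.T
        noise[start:stop] = root @ noise[start:stop]
        start = stop

    freqs = panel.freqs()
    het = 2 * freqs * (1 - freqs)
    het = np.clip(het, 1e-6, None)
    sumstats: dict[str, pd.DataFrame] = {}
    for d in range(k):
        n_d = cfg.n_gwas_per_disorder[d]
        z = np.sqrt(n_d) * smeared[:, d] + noise[:, d]
        se = 1.0 / np.sqrt(n_d * het)
        beta = z * se
        p = np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
        df = panel.variants[["chrom", "pos", "id", "a1", "a2"]].rename(
            columns={"chrom": "CHR", "pos": "POS", "id": "SNP", "a1": "A1", "a2": "A2"}
        )
        df["BETA"] = beta
        df["SE"] = se
        df["P"] = p
        df["N"] = n_d
        df["INFO"] = 1.0
        df["FREQ"] = freqs
        name = DISORDERS[d] if d < len(DISORDERS) else f"trait{d + 1}"
        sumstats[name] = df

    truth = truth or TruthRecord(cfg)
    truth.true_effects = b
    truth.factor_effects = eta
    return sumstats, truth


# ---------------------------------------------------------------------------
# expression atlas
# ---------------------------------------------------------------------------


def simulate_expression_atlas(
    config: SimulationConfig, truth: TruthRecord | None = None
):
    """Six-region developmental expression atlas with planted timing classes.

    Each donor contributes one sample per region.  On the log2 scale a gene's
    value is ``mu_g + donor_intercept + timing_shift + noise``; planted
    prenatal genes sit ``expr_effect`` sample-level standard deviations above
    their postnatal mean (postnatal genes the reverse) and the emitted value
    is ``2**y - 1`` (RPKM-like, non-negative).
    """
    from .devexpr import ExpressionAtlas

    cfg = config
    if cfg.n_donors_pre < 2 or cfg.n_donors_post < 2:
        raise ValueError("need at least 2 donors per developmental window")
    rng = np.random.default_rng([cfg.seed, _RNG_ATLAS])
    genes = gene_ids(cfg.n_genes)
    total_sd = float(np.hypot(cfg.expr_donor_sd, cfg.expr_noise_sd))
    shift = cfg.expr_effect * total_sd / 2.0

    donors = [f"D_PRE{i + 1:03d}" for i in range(cfg.n_donors_pre)] + [
        f"D_POST{i + 1:03d}" for i in range(cfg.n_donors_post)
    ]
    prenatal_flags = [True] * cfg.n_donors_pre + [False] * cfg.n_donors_post
    ages = np.concatenate(
        [
            -rng.uniform(0.1, 0.5, cfg.n_donors_pre),  # fetal, years pre-birth
            rng.uniform(1.0, 40.0, cfg.n_donors_post),
        ]
    )

    mu = rng.uniform(2.0, 8.0, cfg.n_genes)
    donor_u = rng.normal(0.0, cfg.expr_donor_sd, len(donors))

    class_rows = []
    n_pre = int(round(cfg.prop_prenatal * cfg.n_genes))
    n_post = int(round(cfg.prop_postnatal * cfg.n_genes))
    region_class: dict[str, np.ndarray] = {}
    for region in cfg.regions:
        perm = rng.permutation(cfg.n_genes)
        classes = np.array(["continuous"] * cfg.n_genes, dtype=object)
        classes[perm[:n_pre]] = "prenatal"
        classes[perm[n_pre : n_pre + n_post]] = "postnatal"
        region_class[region] = classes
        for g, c in zip(genes, classes):
            class_rows.append((region, g, c))

    sample_ids, meta_rows = [], []
    cols = []
    for di, donor in enumerate(donors):
        for region in cfg.regions:
            sid = f"{donor}_{region}"
            sample_ids.append(sid)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "donor_id": donor,
                    "region": region,
                    "age": float(ages[di]),
                    "prenatal": bool(prenatal_flags[di]),
                }
            )
            classes = region_class[region]
            sign = np.where(
                classes == "prenatal", 1.0, np.where(classes == "postnatal", -1.0, 0.0)
            )
            direction = 1.0 if prenatal_flags[di] else -1.0
            y = (
                mu
                + donor_u[di]
                + direction * sign * shift
                + rng.normal(0.0, cfg.expr_noise_sd, cfg.n_genes)
            )
            cols.append(np.maximum(np.exp2(y) - 1.0, 0.0))

    expression = pd.DataFrame(
        np.column_stack(cols), index=genes, columns=sample_ids
    )
    meta = pd.DataFrame(meta_rows)
    atlas = ExpressionAtlas(expression=expression, samples=meta)
    truth = truth or TruthRecord(cfg)
    truth.gene_classes = pd.DataFrame(
        class_rows, columns=["region", "gene", "class"]
    )
    return atlas, truth


# ---------------------------------------------------------------------------
# gene map
# ---------------------------------------------------------------------------


def simulate_gene_map(
    config: SimulationConfig, panel: GenotypePanel, truth: TruthRecord | None = None
) -> tuple[pd.DataFrame, TruthRecord]:
    """Non-overlapping gene intervals tiled over the panel's coordinate range.

    The range is cut into ``n_genes`` equal slots and one gene with a random
    start/length is placed strictly inside each slot, so intervals are
    pairwise disjoint by construction.  Coordinates are 1-based inclusive.
    """
    cfg = config
    if cfg.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng([cfg.seed, _RNG_GENEMAP])
    max_pos = int(panel.variants["pos"].max()) + cfg.snp_spacing_bp
    slot = max_pos // cfg.n_genes
    if slot < 4:
        raise ValueError(
            f"{cfg.n_genes} genes do not fit in coordinate range 1..{max_pos}"
        )
    ids = gene_ids(cfg.n_genes)
    starts, ends = [], []
    for g in range(cfg.n_genes):
        lo = g * slot + 1
        hi = (g + 1) * slot
        start = int(rng.integers(lo, lo + slot // 4))
        end = int(rng.integers(start + slot // 4, hi))
        starts.append(start)
        ends.append(min(end, hi))
    strands = np.where(rng.random(cfg.n_genes) < 0.5, "+", "-")
    gene_map = pd.DataFrame(
        {
            "gene_id": ids,
            "chrom": str(panel.variants["chrom"].iloc[0]),
            "start": starts,
            "end": ends,
            "strand": strands,
        }
    )
    truth = truth or TruthRecord(cfg)
    truth.gene_map = gene_map
    return gene_map, truth


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def simulate_phenotypes(
    config: SimulationConfig, panel: GenotypePanel, truth: TruthRecord
) -> pd.DataFrame:
    """Twelve correlated psychopathology scales with a planted partitioned
    genetic effect on the Total scale.

    The scales are Cholesky-mixed to the target correlation matrix; a share
    ``pgs_effect_r2`` of the Total scale's variance is replaced by the true
    genetic score of SNPs annotated to the causal (region, class) partition.
    Age, sex, site and five ancestry PCs are generated and stored; the
    clinical flag marks Total T-scores at or above 64.
    """
    from .genemap import annotate_snps_to_genes

    cfg = config
    region, klass = cfg.causal_partition
    if truth.gene_map is None or truth.gene_classes is None:
        raise ValueError("truth must carry gene_map and gene_classes first")
    if truth.factor_effects is None:
        raise ValueError("truth must carry factor effects (simulate sumstats first)")
    tc = cfg.pheno_target_corr
    eig = np.linalg.eigvalsh((tc + tc.T) / 2)
    if eig.min() < -1e-10:
        raise ValueError(
            "pheno_target_corr is not positive-semidefinite; clip its "
            "eigenvalues at zero and renormalize to get the nearest PSD matrix"
        )

    rng = np.random.default_rng([cfg.seed, _RNG_PHENO])
    n = panel.n_samples

    gc = truth.gene_classes
    causal_genes = gc[(gc["region"] == region) & (gc["class"] == klass)]["gene"]
    sub_map = truth.gene_map[truth.gene_map["gene_id"].isin(set(causal_genes))]
    snp2gene, _ = annotate_snps_to_genes(panel.variants, sub_map)
    causal_idx = sorted(
        panel.variants.index[panel.variants["id"].isin(set(snp2gene["snp"]))]
    )
    x = panel.standardized()
    ndv = list(FACTORS).index("NDV")
    if causal_idx and cfg.pgs_effect_r2 > 0:
        g = x[:, causal_idx] @ truth.factor_effects[causal_idx, ndv]
        g = (g - g.mean()) / (g.std() or 1.0)
    else:
        g = np.zeros(n)

    chol = np.linalg.cholesky(
        (tc + tc.T) / 2 + 1e-10 * np.eye(len(SCALES))
    )
    latent = rng.standard_normal((n, len(SCALES))) @ chol.T

    r2 = cfg.pgs_effect_r2
    total_ix = list(SCALES).index("total")
    scales = latent.copy()
    if r2 > 0 and causal_idx:
        scales[:, total_ix] = np.sqrt(r2) * g + np.sqrt(1 - r2) * latent[:, total_ix]

    sites = rng.integers(0, cfg.n_sites, n)
    site_u = rng.normal(0.0, np.sqrt(cfg.site_var), cfg.n_sites)
    scales = np.sqrt(1 - cfg.site_var) * scales + site_u[sites][:, None]

    tscores = 50.0 + 10.0 * scales
    pheno = pd.DataFrame(tscores, columns=list(SCALES))
    pheno.insert(0, "sample_id", panel.samples)
    pheno["age"] = rng.uniform(9.0, 11.0, n)
    pheno["sex"] = rng.integers(0, 2, n)
    pheno["site"] = np.array([f"site{s + 1:02d}" for s in sites], dtype=object)
    for i in range(5):
        pheno[f"PC{i + 1}"] = rng.standard_normal(n)
    pheno["clinical"] = pheno["total"] >= CLINICAL_CUTOFF

    truth.liability = g
    truth.causal_snps = sorted(set(snp2gene["snp"]))
    return pheno


# ---------------------------------------------------------------------------
# orchestration and writers
# ---------------------------------------------------------------------------


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate a full synthetic study (panel, GWAS, atlas, gene map,
    phenotypes) with a shared :class:`TruthRecord`."""
    panel = simulate_genotypes(config)
    gene_map, truth = simulate_gene_map(config, panel)
    sumstats, truth = simulate_multitrait_sumstats(config, panel, truth)
    atlas, truth = simulate_expression_atlas(config, truth)
    phenotypes = simulate_phenotypes(config, panel, truth)
    return SimulatedStudy(panel, sumstats, atlas, gene_map, phenotypes, truth)


def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    """Write every simulated dataset in its standard on-disk format."""
    from .genemap import write_gene_map

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_plink(study.panel, outdir / "panel")
    for name, df in study.sumstats.items():
        write_sumstats(df, outdir / f"sumstats_{name}.tsv")
    write_gene_map(study.gene_map, outdir / "genes.bed")
    study.atlas.expression.to_csv(outdir / "atlas_expression.tsv", sep="\t")
    study.atlas.samples.to_csv(outdir / "atlas_samples.tsv", sep="\t", index=False)
    study.phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
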