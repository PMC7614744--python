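"""Simulation configuration for the synthetic developmental-PGS cohort.

Defaults describe the study conditions the pipeline is designed for: eight
psychiatric-disorder GWAS whose genetic covariance follows three correlated
latent factors (a neurodevelopmental factor loading ADHD, ASD, MDD and
Tourette syndrome; a compulsive factor loading anorexia, OCD and Tourette;
a mood-psychotic factor loading bipolar, MDD and schizophrenia), an
LD-blocked genotype panel in Hardy-Weinberg equilibrium, a six-region
developmental expression atlas with planted prenatal-peak / postnatal-peak
genes, and twelve correlated psychopathology scales on a T-score-like
metric with the clinical range at Total >= 64.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REGIONS = ("CBC", "AMY", "MDTHAL", "STR", "HIP", "NCX")

DISORDERS = ("ADHD", "ASD", "MDD", "TS", "AN", "OCD", "BIP", "SCZ")

FACTORS = ("NDV", "COMP", "MP")

#: 11 CBCL-like scales plus one child-reported psychosis scale
SCALES = (
    "anxdep",
    "withdep",
    "somatic",
    "social",
    "thought",
    "attention",
    "rulebreak",
    "aggressive",
    "internalizing",
    "externalizing",
    "total",
    "psychosis",
)

CLINICAL_CUTOFF = 64.0  # T-score clinical range, Total scale


def default_factor_loadings() -> np.ndarray:
    """Disorders x factors loading matrix mirroring the three-cluster
    structure (rows ordered as :data:`DISORDERS`, columns as
    :data:`FACTORS`)."""
    lam = np.zeros((8, 3))
    idx = {d: i for i, d in enumerate(DISORDERS)}
    # NDV: ADHD, ASD, MDD, TS
    lam[idx["ADHD"], 0] = 0.70
    lam[idx["ASD"], 0] = 0.60
    lam[idx["MDD"], 0] = 0.50
    lam[idx["TS"], 0] = 0.40
    # COMP: AN, OCD, TS
    lam[idx["AN"], 1] = 0.60
    lam[idx["OCD"], 1] = 0.70
    lam[idx["TS"], 1] = 0.45
    # MP: BIP, MDD, SCZ
    lam[idx["BIP"], 2] = 0.70
    lam[idx["MDD"], 2] = 0.45
    lam[idx["SCZ"], 2] = 0.75
    return lam


def default_factor_corr() -> np.ndarray:
    return np.array(
        [
            [1.0, 0.3, 0.4],
            [0.3, 1.0, 0.3],
            [0.4, 0.3, 1.0],
        ]
    )


def default_pheno_corr() -> np.ndarray:
    """Default 12x12 scale correlation matrix.

    One shared-factor structure: the 11 CBCL-like scales load 0.55-0.92 so
    their pairwise correlations fall in ~0.30-0.85; the psychosis-like scale
    loads weakly (pairwise correlations ~0.08-0.13), matching the pattern of
    moderate-to-strong CBCL inter-correlations and a weakly coupled
    child-reported psychosis measure.
    """
    loadings = np.array(
        [0.62, 0.58, 0.55, 0.66, 0.64, 0.68, 0.70, 0.78, 0.85, 0.88, 0.92, 0.145]
    )
    corr = np.outer(loadings, loadings)
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort generator.

    Attributes follow the pipeline's units: positions in base pairs,
    heritability on [0, 1], expression shifts in sample-level standard
    deviations, phenotypes on a T-score-like scale (mean 50, sd 10).
    """

    n_individuals: int = 2000
    n_snps: int = 5000
    n_genes: int = 500
    ld_block_size: int = 8
    #: adjacent-SNP latent AR correlation within a block; a scalar applies
    #: to every block, a (lo, hi) pair draws each block's value uniformly.
    #: LD strength varies widely along real genomes (from near-independent
    #: stretches to near-duplicate markers); the wide default range also
    #: gives LD scores the spread that LD-score regression needs for slope
    #: and intercept identification.
    ld_rho: float | tuple[float, float] = (0.0, 0.995)
    maf_range: tuple[float, float] = (0.05, 0.5)
    #: inter-SNP spacing; genotyping-array-like density (~300k markers on a
    #: 3 Gb genome)
    snp_spacing_bp: int = 10_000
    missing_rate: float = 0.0

    n_disorders: int = 8
    factor_loadings: np.ndarray = field(default_factory=default_factor_loadings)
    factor_corr: np.ndarray = field(default_factory=default_factor_corr)
    h2_per_disorder: np.ndarray = field(default_factory=lambda: np.full(8, 0.4))
    n_gwas_per_disorder: np.ndarray = field(
        default_factory=lambda: np.full(8, 50_000)
    )

    regions: tuple[str, ...] = REGIONS
    prop_prenatal: float = 0.20
    prop_postnatal: float = 0.23
    expr_effect: float = 1.5
    n_donors_pre: int = 20
    n_donors_post: int = 20
    expr_donor_sd: float = 0.5
    expr_noise_sd: float = 1.0

    pheno_target_corr: np.ndarray = field(default_factory=default_pheno_corr)
    causal_partition: tuple[str, str] = ("CBC", "prenatal")
    pgs_effect_r2: float = 0.02
    n_sites: int = 22
    site_var: float = 0.02

    seed: int = 0

    def __post_init__(self) -> None:
        self.factor_loadings = np.asarray(self.factor_loadings, dtype=float)
        self.factor_corr = np.asarray(self.factor_corr, dtype=float)
        self.h2_per_disorder = np.broadcast_to(
            np.asarray(self.h2_per_disorder, dtype=float), (self.n_disorders,)
        ).copy()
        self.n_gwas_per_disorder = np.broadcast_to(
            np.asarray(self.n_gwas_per_disorder, dtype=float), (self.n_disorders,)
        ).copy()
        self.pheno_target_corr = np.asarray(self.pheno_target_corr, dtype=float)

        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        rho = np.atleast_1d(np.asarray(self.ld_rho, dtype=float))
        if rho.size not in (1, 2) or np.any(rho < 0) or np.any(rho >= 1):
            raise ValueError("ld_rho must lie in [0, 1) (scalar or (lo, hi) pair)")
        if rho.size == 2 and rho[0] > rho[1]:
            raise ValueError("ld_rho range must satisfy lo <= hi")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.factor_loadings.shape[0] != self.n_disorders:
            raise ValueError("factor_loadings rows must equal n_disorders")
        phi = self.factor_corr
        if not np.allclose(phi, phi.T) or not np.allclose(np.diag(phi), 1.0):
            raise ValueError("factor_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(phi).min() <= 0:
            raise ValueError("factor_corr must be positive-definite")
        if self.prop_prenatal + self.prop_postnatal > 1:
            raise ValueError("prop_prenatal + prop_postnatal must be <= 1")
        if np.any(self.h2_per_disorder < 0) or np.any(self.h2_per_disorder > 1):
            raise ValueError("h2_per_disorder must lie in [0, 1]")
        tc = self.pheno_target_corr
        if tc.shape != (len(SCALES), len(SCALES)):
            raise ValueError(f"pheno_target_corr must be {len(SCALES)}x{len(SCALES)}")
        if np.linalg.eigvalsh((tc + tc.T) / 2).min() < -1e-10:
            raise ValueError(
                "pheno_target_corr must be positive-semidefinite; project it "
                "to the nearest PSD matrix (eigenvalue clipping) first"
            )
        communality = np.einsum(
            "df,fg,dg->d", self.factor_loadings, phi, self.factor_loadings
        )
        if np.any(communality > 1 + 1e-9):
            raise ValueError(
                "factor loadings imply per-disorder genetic variance > 1"
            )
        if self.causal_partition[0] not in self.regions or self.causal_partition[
            1
        ] not in ("prenatal", "postnatal", "continuous"):
            raise ValueError("causal_partition must name a (region, class) pair")

    @property
    def communalities(self) -> np.ndarray:
        return np.einsum(
            "df,fg,dg->d", self.factor_loadings, self.factor_corr, self.factor_loadings
        )
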