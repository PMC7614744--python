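"""Windowed SNP-to-gene annotation, gene-level association and
tissue-specificity gene-property regression.

Annotation windows are strand-aware: a plus-strand gene spanning [s, e]
captures SNPs in [s - up_kb, e + down_kb]; a minus-strand gene captures
[s - down_kb, e + up_kb].  The gene-level statistic is the SNP-wise mean
chi-square, referenced to the LD-eigenvalue-weighted mixture of 1-df
chi-squares via a moment-matched gamma (Satterthwaite) approximation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .assoc import bh_fdr

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# gene map I/O (BED-like on disk: 0-based half-open; 1-based inclusive here)
# ---------------------------------------------------------------------------


def write_gene_map(gene_map: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "chrom": gene_map["chrom"],
            "start": gene_map["start"] - 1,
            "end": gene_map["end"],
            "gene_id": gene_map["gene_id"],
            "score": 0,
            "strand": gene_map["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_gene_map(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str, "gene_id": str, "strand": str},
    )
    df["start"] = df["start"] + 1  # to 1-based inclusive
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"unknown strand symbols: {sorted(df['strand'][bad].unique())}")
    return df[["gene_id", "chrom", "start", "end", "strand"]]


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def annotate_snps_to_genes(
    variants: pd.DataFrame,
    gene_map: pd.DataFrame,
    up_kb: float = 35.0,
    down_kb: float = 10.0,
    ignore_strand: bool = False,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Assign SNPs to genes using strand-aware upstream/downstream windows.

    ``variants`` needs columns ``chrom, pos, id`` (or CHR/POS/SNP);
    a SNP may map to multiple genes.  Returns ``(snp2gene long table,
    gene -> [snp ids] dict)``.
    """
    v = variants.rename(
        columns={"CHR": "chrom", "POS": "pos", "SNP": "id"}
    )
    up = up_kb * 1000.0
    down = down_kb * 1000.0
    bad = ~gene_map["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(
            f"unknown strand symbols: {sorted(gene_map['strand'][bad].unique())}"
        )
    rows = []
    gene_snps: dict[str, list[str]] = {}
    pos = v["pos"].to_numpy()
    ids = v["id"].to_numpy()
    chrom = v["chrom"].to_numpy().astype(str)
    for _, gene in gene_map.iterrows():
        if ignore_strand or gene["strand"] == "+":
            lo, hi = gene["start"] - up, gene["end"] + down
        else:
            lo, hi = gene["start"] - down, gene["end"] + up
        mask = (chrom == str(gene["chrom"])) & (pos >= lo) & (pos <= hi)
        snps = list(ids[mask])
        gene_snps[gene["gene_id"]] = snps
        rows.extend((s, gene["gene_id"]) for s in snps)
    snp2gene = pd.DataFrame(rows, columns=["snp", "gene"])
    return snp2gene, gene_snps


# ---------------------------------------------------------------------------
# SNP-wise mean gene test
# ---------------------------------------------------------------------------


def _mixture_pvalue(stat: float, eigenvalues: np.ndarray) -> float:
    """Tail probability of sum(lambda_i chi2_1) >= stat via a moment-matched
    gamma (Satterthwaite) approximation."""
    mu = float(eigenvalues.sum())
    var = float(2.0 * (eigenvalues**2).sum())
    if mu <= 0 or var <= 0:
        return 1.0
    shape = mu * mu / var
    scale = var / mu
    return float(stats.gamma.sf(stat, a=shape, scale=scale))


def _mixture_pvalue_mc(
    stat: float, eigenvalues: np.ndarray, n_draws: int = 100_000, seed: int = 0
) -> float:
    """Monte-Carlo tail probability of the eigenvalue mixture (validation)."""
    rng = np.random.default_rng(seed)
    draws = rng.chisquare(1.0, size=(n_draws, len(eigenvalues))) @ eigenvalues
    return float((1 + np.sum(draws >= stat)) / (1 + n_draws))


def gene_snpwise_mean_test(
    factor_sumstats: pd.DataFrame,
    assignments: pd.DataFrame,
    ld_panel,
    ridge: float = 1e-6,
    null_method: str = "satterthwaite",
    mc_draws: int = 100_000,
) -> pd.DataFrame:
    """SNP-wise mean gene-level association test.

    For each gene, ``T = mean(chi2)`` over its SNPs; ``k T`` is referenced
    to ``sum(lambda_i chi2_1)`` with eigenvalues of the SNPs' dosage
    correlation matrix (ridge-regularized).  Benjamini-Hochberg q-values
    are computed across genes.  ``assignments`` is the snp/gene long table
    from :func:`annotate_snps_to_genes`.
    """
    ss = factor_sumstats.set_index("SNP")
    z2 = (ss["BETA"] / ss["SE"]) ** 2
    var_index = {vid: i for i, vid in enumerate(ld_panel.variants["id"])}
    x = ld_panel.standardized()
    n = ld_panel.n_samples

    rows = []
    for gene, grp in assignments.groupby("gene", sort=True):
        snps = [s for s in grp["snp"] if s in z2.index and s in var_index]
        if not snps:
            log.warning("gene %s has no scored SNPs; omitted", gene)
            continue
        idx = [var_index[s] for s in snps]
        k = len(idx)
        chi2 = z2.loc[snps].to_numpy(float)
        t_mean = float(chi2.mean())
        sub = x[:, idx]
        corr = sub.T @ sub / n + ridge * np.eye(k)
        eig = np.clip(np.linalg.eigvalsh(corr), 0, None)
        if null_method == "montecarlo":
            p = _mixture_pvalue_mc(
                k * t_mean, eig, n_draws=mc_draws, seed=abs(hash(gene)) % (2**31)
            )
        else:
            p = _mixture_pvalue(k * t_mean, eig)
        rows.append((gene, k, t_mean, max(p, 1e-300)))
    out = pd.DataFrame(rows, columns=["gene", "n_snps", "mean_chi2", "p"])
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# tissue-specificity gene-property regression
# ---------------------------------------------------------------------------


def gene_property_tissue_regression(
    gene_assoc: pd.DataFrame,
    tissue_expression: pd.DataFrame,
    gene_lengths: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-tissue one-sided gene-property regression.

    Gene association p-values are converted to z-scores (probit of 1 - p)
    and regressed, per tissue, on that tissue's log expression, covarying
    the average log expression across tissues, log gene length and log SNP
    count.  The one-sided p tests a positive expression coefficient
    (tissue specificity of association); the Bonferroni threshold
    ``0.05 / n_tissues`` is attached.
    """
    genes = [g for g in gene_assoc["gene"] if g in tissue_expression.index]
    ga = gene_assoc.set_index("gene").loc[genes]
    zscore = stats.norm.isf(np.clip(ga["p"].to_numpy(float), 1e-300, 1 - 1e-16))
    logexpr = np.log2(tissue_expression.loc[genes].to_numpy(float) + 1.0)
    avg = logexpr.mean(axis=1)
    log_nsnps = np.log(ga["n_snps"].to_numpy(float))
    if gene_lengths is not None:
        log_len = np.log(gene_lengths.loc[genes].to_numpy(float))
    else:
        log_len = np.zeros(len(genes))

    tissues = list(tissue_expression.columns)
    rows = []
    for t_i, tissue in enumerate(tissues):
        expr_t = logexpr[:, t_i]
        if np.allclose(expr_t, expr_t[0]):
            log.warning("tissue %s has constant expression; skipped", tissue)
            continue
        covars = [avg, log_nsnps]
        if gene_lengths is not None:
            covars.append(log_len)
        design = sm.add_constant(np.column_stack([expr_t] + covars))
        fit = sm.OLS(zscore, design).fit()
        beta = fit.params[1]
        p_one = float(stats.t.sf(fit.tvalues[1], fit.df_resid))
        rows.append((tissue, float(beta), float(fit.bse[1]), p_one))
    out = pd.DataFrame(rows, columns=["tissue", "beta", "se", "p_one_sided"])
    out["bonferroni_threshold"] = 0.05 / max(len(out), 1)
    return out
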