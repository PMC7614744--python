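"""Polygenic scoring by clumping and thresholding, and the 18
developmental-timing-partitioned scores (3 timing classes x 6 regions).

A PGS is the per-individual sum of effect-allele dosages weighted by GWAS
betas over approximately independent index SNPs (greedy p-value-ordered
clumping under an LD r2 ceiling within a genomic window).  A partitioned
PGS (pPGS) restricts the SNP set to variants annotated to genes of one
developmental-timing class within one brain region before clumping and
scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypePanel

log = logging.getLogger(__name__)

DEFAULT_PT_GRID = (0.001, 0.01, 0.05, 0.1, 0.5, 1.0)


@dataclass
class ScoreMatrix:
    """Individuals x score columns with per-column metadata.

    ``scores`` holds raw values (index: sample id); ``meta`` one row per
    column (source, Pt threshold, optional partition region/class);
    ``standardized`` and ``quintiles`` are filled by
    :func:`standardize_and_quintile`.
    """

    scores: pd.DataFrame
    meta: pd.DataFrame
    standardized: pd.DataFrame | None = None
    quintiles: pd.DataFrame | None = None
    flags: dict = field(default_factory=dict)


def _aligned_effects(
    panel: GenotypePanel, sumstats: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Match sumstats to panel variants, flipping swapped alleles.

    Returns (panel column indices, betas, p-values, n_dropped); a swapped
    a1/a2 orientation flips the dosage (2 - d), implemented by negating the
    dosage sign bookkeeping downstream.
    """
    var = panel.variants
    key = {
        (i_id, a1, a2): j
        for j, (i_id, a1, a2) in enumerate(zip(var["id"], var["a1"], var["a2"]))
    }
    idx, betas, pvals, flip = [], [], [], []
    dropped = 0
    for snp, a1, a2, beta, p in zip(
        sumstats["SNP"], sumstats["A1"], sumstats["A2"], sumstats["BETA"], sumstats["P"]
    ):
        j = key.get((snp, a1, a2))
        if j is not None:
            idx.append(j)
            betas.append(beta)
            pvals.append(p)
            flip.append(False)
            continue
        j = key.get((snp, a2, a1))
        if j is not None:
            idx.append(j)
            betas.append(beta)
            pvals.append(p)
            flip.append(True)
            continue
        dropped += 1
    return (
        np.array(idx, dtype=int),
        np.array(betas, dtype=float),
        np.array(pvals, dtype=float),
        np.array(flip, dtype=bool),
        dropped,
    )


def clump(
    sumstats: pd.DataFrame,
    ld_panel: GenotypePanel,
    r2: float = 0.1,
    window_kb: float = 250.0,
) -> pd.DataFrame:
    """Greedy p-value-ordered LD clumping; returns the index-SNP sumstats.

    Candidates are visited by ascending p (ties broken by position, then
    id) and accepted when their squared dosage correlation with every
    previously accepted SNP within ``window_kb`` is at most ``r2``.  SNPs
    absent from the panel are dropped (counted in the log).
    """
    var = ld_panel.variants
    in_panel = sumstats["SNP"].isin(set(var["id"]))
    n_drop = int((~in_panel).sum())
    if n_drop:
        log.warning("%d sumstat SNPs absent from LD panel; dropped", n_drop)
    ss = sumstats[in_panel].copy()
    panel_pos = dict(zip(var["id"], var["pos"]))
    panel_chrom = dict(zip(var["id"], var["chrom"]))
    panel_idx = {vid: j for j, vid in enumerate(var["id"])}
    ss["_pos"] = ss["SNP"].map(panel_pos)
    ss["_chrom"] = ss["SNP"].map(panel_chrom)
    ss = ss.sort_values(["P", "_pos", "SNP"], kind="stable")

    x = ld_panel.standardized()
    n = ld_panel.n_samples
    window = window_kb * 1000.0
    m_cand = len(ss)
    chrom_codes = {c: i for i, c in enumerate(ss["_chrom"].unique())}
    cand_idx = np.array([panel_idx[s] for s in ss["SNP"]], dtype=int)
    cand_pos = ss["_pos"].to_numpy(dtype=float)
    cand_chrom = np.array([chrom_codes[c] for c in ss["_chrom"]], dtype=int)
    acc_idx = np.empty(m_cand, dtype=int)
    acc_pos = np.empty(m_cand, dtype=float)
    acc_chrom = np.empty(m_cand, dtype=int)
    n_acc = 0
    keep_rows = []
    for row_i in range(m_cand):
        j = cand_idx[row_i]
        ok = True
        if n_acc:
            near = np.flatnonzero(
                (np.abs(acc_pos[:n_acc] - cand_pos[row_i]) <= window)
                & (acc_chrom[:n_acc] == cand_chrom[row_i])
            )
            if near.size:
                r = x[:, acc_idx[near]].T @ x[:, j] / n
                ok = bool(np.all(r * r <= r2))
        if ok:
            acc_idx[n_acc] = j
            acc_pos[n_acc] = cand_pos[row_i]
            acc_chrom[n_acc] = cand_chrom[row_i]
            n_acc += 1
            keep_rows.append(row_i)
    out = ss.iloc[keep_rows].drop(columns=["_pos", "_chrom"])
    return out.sort_values(["CHR", "POS"]).reset_index(drop=True)


def score(
    panel: GenotypePanel,
    clumped_sumstats: pd.DataFrame,
    pt_grid=DEFAULT_PT_GRID,
    source: str = "PGS",
    column_prefix: str | None = None,
    partition: tuple[str, str] | None = None,
) -> ScoreMatrix:
    """Weighted-allele scoring across a grid of p-value thresholds.

    ``score_i = sum_{p_j <= Pt} beta_j * dosage_ij`` with missing dosages
    imputed as twice the panel allele frequency; sumstat alleles are
    aligned to the panel (a swapped orientation scores ``2 - dosage``).
    """
    idx, betas, pvals, flip, dropped = _aligned_effects(panel, clumped_sumstats)
    if dropped:
        log.warning("%d sumstat SNPs not alignable to panel; dropped", dropped)
    prefix = column_prefix or source
    meta_rows, cols = [], {}
    freqs = panel.freqs()
    d = panel.dosages.astype(float)
    for pt in np.atleast_1d(pt_grid):
        sel = pvals <= pt
        name = f"{prefix}_pt{pt:g}"
        if not sel.any():
            log.warning("no SNPs at Pt=%g; column of zeros emitted", pt)
            cols[name] = np.zeros(panel.n_samples)
        else:
            sub_idx = idx[sel]
            dose = d[:, sub_idx].copy()
            fr = freqs[sub_idx]
            miss = dose == MISSING
            dose[miss] = np.broadcast_to(2 * fr, dose.shape)[miss]
            dose[:, flip[sel]] = 2.0 - dose[:, flip[sel]]
            cols[name] = dose @ betas[sel]
        meta_rows.append(
            {
                "column": name,
                "source": source,
                "pt": float(pt),
                "region": partition[0] if partition else None,
                "class": partition[1] if partition else None,
                "n_snps": int(sel.sum()),
            }
        )
    scores = pd.DataFrame(cols, index=pd.Index(panel.samples, name="sample_id"))
    return ScoreMatrix(scores=scores, meta=pd.DataFrame(meta_rows))


def standardize_and_quintile(matrix: ScoreMatrix) -> ScoreMatrix:
    """Z-standardize each score column and assign quintiles 1-5.

    Quintile boundaries sit at the empirical 20/40/60/80 percentiles,
    realized by a stable sort split into five near-equal groups (ties keep
    input order), so group sizes differ by at most one.  Zero-variance
    columns are flagged and skipped.
    """
    if len(matrix.scores) < 5:
        raise ValueError("need at least 5 individuals for quintiles")
    std = pd.DataFrame(index=matrix.scores.index)
    quint = pd.DataFrame(index=matrix.scores.index)
    for col in matrix.scores.columns:
        vals = matrix.scores[col].to_numpy(float)
        sd = vals.std()
        if sd == 0:
            matrix.flags[col] = "zero_variance"
            continue
        std[col] = (vals - vals.mean()) / sd
        order = np.argsort(vals, kind="stable")
        groups = np.array_split(order, 5)
        q = np.empty(len(vals), dtype=int)
        for g_i, g in enumerate(groups):
            q[g] = g_i + 1
        quint[col] = q
    matrix.standardized = std
    matrix.quintiles = quint
    return matrix


def partition_sumstats_and_score(
    factor_sumstats: pd.DataFrame,
    assignments: pd.DataFrame,
    partitions: pd.DataFrame,
    panel: GenotypePanel,
    regions=None,
    classes=("prenatal", "postnatal", "continuous"),
    r2: float = 0.1,
    window_kb: float = 250.0,
    pt: float = 1.0,
    source: str = "NDV",
) -> ScoreMatrix:
    """Build the 18 developmental-timing-partitioned PGS columns.

    For each (region, timing class), the SNP subset contains every variant
    annotated to at least one gene of that class in that region
    (``assignments``: snp/gene long table; ``partitions``: region, gene,
    class).  Each subset is clumped independently and scored at ``pt``.  A
    SNP mapping to genes of several classes appears in every matching
    partition.
    """
    regions = list(regions) if regions is not None else sorted(
        partitions["region"].unique()
    )
    gene2snps = assignments.groupby("gene")["snp"].agg(set)
    all_scores, all_meta = [], []
    for region in regions:
        part = partitions[partitions["region"] == region]
        for klass in classes:
            genes = part[part["class"] == klass]["gene"]
            snps: set[str] = set()
            for g in genes:
                snps |= gene2snps.get(g, set())
            name = f"{source}_{region}_{klass}"
            if not snps:
                log.warning("empty partition %s/%s; zero column", region, klass)
                col = pd.DataFrame(
                    {name: np.zeros(panel.n_samples)},
                    index=pd.Index(panel.samples, name="sample_id"),
                )
                all_scores.append(col)
                all_meta.append(
                    {
                        "column": name,
                        "source": source,
                        "pt": pt,
                        "region": region,
                        "class": klass,
                        "n_snps": 0,
                    }
                )
                continue
            subset = factor_sumstats[factor_sumstats["SNP"].isin(snps)]
            clumped = clump(subset, panel, r2=r2, window_kb=window_kb)
            sm_ = score(
                panel,
                clumped,
                pt_grid=(pt,),
                source=source,
                column_prefix=name,
                partition=(region, klass),
            )
            col = sm_.scores
            col.columns = [name]
            all_scores.append(col)
            meta = sm_.meta.iloc[0].to_dict()
            meta["column"] = name
            all_meta.append(meta)
    scores = pd.concat(all_scores, axis=1)
    return ScoreMatrix(scores=scores, meta=pd.DataFrame(all_meta))
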