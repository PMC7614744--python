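"""Developmental (pre- versus postnatal) expression models and per-gene
timing classification per brain region.

The atlas is a genes x samples expression matrix (RPKM-like, non-negative)
with sample metadata (donor, region, age, prenatal flag).  Expression is
log2(x + 1)-transformed before modelling.  Two operations:

* :func:`set_prepost_mixed_model` — a gene-set-level mixed model
  ``expr = gamma00 + beta1 * prenatal + u_gene + u_donor + eps`` with
  crossed random intercepts for gene and donor (REML); positive ``beta1``
  means higher prenatal expression (prenatal coded 1).
* :func:`classify_genes_prepost` — per-gene Welch t-tests of prenatal vs
  postnatal donor means with Benjamini-Hochberg FDR; genes with q < 0.05
  and a positive (negative) prenatal-minus-postnatal estimate are classed
  prenatal (postnatal), everything else continuous.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .assoc import bh_fdr

log = logging.getLogger(__name__)

TIMING_CLASSES = ("prenatal", "postnatal", "continuous")


@dataclass
class ExpressionAtlas:
    """Region-resolved developmental expression.

    ``expression``: genes x samples DataFrame of non-negative values;
    ``samples``: metadata with columns ``sample_id, donor_id, region, age,
    prenatal``.
    """

    expression: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "donor_id", "region", "age", "prenatal"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
        if not set(self.samples["sample_id"]) <= set(self.expression.columns):
            raise ValueError("metadata sample ids absent from expression matrix")
        if (self.expression.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    def regions(self) -> list[str]:
        return sorted(self.samples["region"].unique())

    def region_samples(self, region: str) -> pd.DataFrame:
        sub = self.samples[self.samples["region"] == region]
        if sub.empty:
            raise ValueError(f"region {region!r} not present in atlas")
        return sub

    def donor_means(self, region: str, log_transform: bool = True) -> pd.DataFrame:
        """Per-donor mean expression in a region (genes x donors), with a
        parallel prenatal flag per donor.  Replicate samples of one donor
        within the region are averaged first."""
        sub = self.region_samples(region)
        expr = self.expression[sub["sample_id"]].to_numpy(float)
        if log_transform:
            expr = np.log2(expr + 1.0)
        frame = pd.DataFrame(
            expr, index=self.expression.index, columns=sub["sample_id"]
        )
        donor_of = dict(zip(sub["sample_id"], sub["donor_id"]))
        means = frame.T.groupby(frame.columns.map(donor_of)).mean().T
        pre_of = sub.groupby("donor_id")["prenatal"].first()
        return means, pre_of.loc[means.columns]


def set_prepost_mixed_model(
    atlas: ExpressionAtlas,
    region: str,
    gene_set: list[str],
    log_transform: bool = True,
) -> dict:
    """REML mixed model of a gene set's pre/postnatal expression contrast.

    Returns a dict with ``beta1`` (prenatal effect; prenatal coded 1),
    ``se``, ``p`` (Wald z), and the estimated variance components.  If a
    variance component collapses to zero the model is refit without it
    (reported in ``dropped_components``).
    """
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    sub = atlas.region_samples(region)
    if sub.groupby("prenatal")["donor_id"].nunique().min() < 2 or sub[
        "prenatal"
    ].nunique() < 2:
        raise ValueError("need >= 2 donors in each developmental window")
    genes = [g for g in gene_set if g in atlas.expression.index]
    expr = atlas.expression.loc[genes, sub["sample_id"]].to_numpy(float)
    if log_transform:
        expr = np.log2(expr + 1.0)
    long = pd.DataFrame(
        {
            "expr": expr.ravel(),
            "gene": np.repeat(genes, len(sub)),
            "donor": np.tile(sub["donor_id"].to_numpy(), len(genes)),
            "prenatal": np.tile(
                sub["prenatal"].to_numpy().astype(float), len(genes)
            ),
        }
    )

    components = ["gene", "donor"]
    dropped: list[str] = []
    while True:
        vc = {c: f"0 + C({c})" for c in components}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "expr ~ prenatal",
                long,
                groups=np.ones(len(long)),
                vc_formula=vc if vc else None,
            )
            fit = model.fit(reml=True)
        if not components:
            break
        # statsmodels orders variance components by sorted vc_formula keys
        vcomp = dict(zip(sorted(components), np.atleast_1d(fit.vcomp)))
        small = [c for c, v in vcomp.items() if v < 1e-8]
        if not small:
            break
        dropped.extend(small)
        components = [c for c in components if c not in small]
        if not components:
            ols = sm.OLS(
                long["expr"], sm.add_constant(long["prenatal"])
            ).fit()
            return {
                "beta1": float(ols.params.iloc[1]),
                "se": float(ols.bse.iloc[1]),
                "p": float(ols.pvalues.iloc[1]),
                "vcomp": {},
                "dropped_components": dropped,
            }
    beta1 = float(fit.params["prenatal"])
    se = float(fit.bse["prenatal"])
    p = float(2 * stats.norm.sf(abs(beta1 / se)))
    return {
        "beta1": beta1,
        "se": se,
        "p": p,
        "vcomp": dict(zip(sorted(components), np.atleast_1d(fit.vcomp))),
        "dropped_components": dropped,
    }


def classify_genes_prepost(
    atlas: ExpressionAtlas,
    region: str,
    q_threshold: float = 0.05,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Classify every gene in a region as prenatal / postnatal / continuous.

    Welch t-tests contrast per-donor mean prenatal vs postnatal expression;
    after Benjamini-Hochberg correction across all genes tested in the
    region, genes with q below the threshold are classed by the sign of the
    prenatal-minus-postnatal estimate, all others continuous.  Genes with
    fewer than 2 donors per window are flagged and classed continuous.
    """
    means, prenatal = atlas.donor_means(region, log_transform=log_transform)
    pre = means.loc[:, prenatal.to_numpy()].to_numpy(float)
    post = means.loc[:, ~prenatal.to_numpy()].to_numpy(float)
    if pre.shape[1] < 2 or post.shape[1] < 2:
        raise ValueError("need >= 2 donors in each developmental window")
    ok_pre = np.isfinite(pre).sum(axis=1) >= 2
    ok_post = np.isfinite(post).sum(axis=1) >= 2
    testable = ok_pre & ok_post

    est = np.nanmean(pre, axis=1) - np.nanmean(post, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pval = stats.ttest_ind(
            pre, post, axis=1, equal_var=False, nan_policy="omit"
        )
    pval = np.asarray(pval, dtype=float)
    # degenerate genes (zero variance in both windows): t undefined -> p 1
    pval[~np.isfinite(pval)] = 1.0
    pval[~testable] = 1.0
    q = np.ones_like(pval)
    q[testable] = bh_fdr(pval[testable])

    classes = np.where(
        (q < q_threshold) & (est > 0),
        "prenatal",
        np.where((q < q_threshold) & (est < 0), "postnatal", "continuous"),
    )
    return pd.DataFrame(
        {
            "region": region,
            "gene": means.index,
            "class": classes,
            "estimate": est,
            "p": pval,
            "q": q,
            "testable": testable,
        }
    )


def classify_all_regions(
    atlas: ExpressionAtlas, q_threshold: float = 0.05, log_transform: bool = True
) -> pd.DataFrame:
    """Concatenated :func:`classify_genes_prepost` over every atlas region."""
    return pd.concat(
        [
            classify_genes_prepost(
                atlas, region, q_threshold=q_threshold, log_transform=log_transform
            )
            for region in atlas.regions()
        ],
        ignore_index=True,
    )
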