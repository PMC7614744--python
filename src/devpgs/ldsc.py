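"""LD-score regression: LD scores, heritability, genetic covariance and the
block-jackknife sampling covariance matrix.

Univariate LDSC regresses per-SNP chi-square statistics on LD scores
(``E[chi2_j] = 1 + n h2 l_j / M`` with a free intercept); the bivariate form
regresses ``z1 * z2`` products, whose slope recovers genetic covariance.
The sampling covariance ``V`` of ``vech(S)`` comes from a delete-one block
jackknife over contiguous SNP blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def vech_indices(k: int) -> list[tuple[int, int]]:
    """Column-major lower-triangle (i >= j) index order used for vech."""
    return [(i, j) for j in range(k) for i in range(j, k)]


def vech(mat: np.ndarray) -> np.ndarray:
    return np.array([mat[i, j] for i, j in vech_indices(mat.shape[0])])


def compute_ld_scores(panel, window_kb: float = 1000.0) -> pd.DataFrame:
    """Windowed LD scores with small-sample-adjusted r-squared.

    ``l_j = sum_k r2_adj(j, k)`` over SNPs within ``window_kb`` on the same
    chromosome (self term included), where
    ``r2_adj = r2 - (1 - r2) / (n - 2)`` removes the E[r2] = 1/(n-1)-scale
    upward bias of the squared sample correlation.
    """
    n = panel.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples for adjusted r-squared")
    x = panel.standardized()
    pos = panel.variants["pos"].to_numpy()
    chrom = panel.variants["chrom"].to_numpy()
    m = panel.n_variants
    window = window_kb * 1000.0
    scores = np.zeros(m)
    chunk = 512
    for a in range(0, m, chunk):
        b = min(a + chunk, m)
        lo = int(np.searchsorted(pos, pos[a] - window))
        hi = int(np.searchsorted(pos, pos[b - 1] + window, side="right"))
        r = x[:, a:b].T @ x[:, lo:hi] / n
        r2 = r * r
        adj = r2 - (1.0 - r2) / (n - 2)
        in_window = (
            np.abs(pos[a:b][:, None] - pos[lo:hi][None, :]) <= window
        ) & (chrom[a:b][:, None] == chrom[lo:hi][None, :])
        scores[a:b] = np.where(in_window, adj, 0.0).sum(axis=1)
    return pd.DataFrame({"SNP": panel.variants["id"].to_numpy(), "L2": scores})


@dataclass
class GeneticCovariance:
    """Genetic covariance matrix S with jackknife sampling covariance V.

    ``S`` is k x k with heritabilities on the diagonal; ``V`` is the
    K x K (K = k(k+1)/2) sampling covariance of ``vech(S)`` in column-major
    lower-triangle order; ``intercepts`` holds the LDSC intercepts
    (univariate on the diagonal, cross-trait off it).
    """

    S: np.ndarray
    V: np.ndarray
    intercepts: np.ndarray
    traits: list[str]
    n_snps: int
    v_smoothed: bool = False

    def smoothed_V(self) -> np.ndarray:
        """Nearest-positive-definite V via eigenvalue flooring."""
        w, q = np.linalg.eigh((self.V + self.V.T) / 2)
        floor = 1e-9 * max(w.max(), 1e-30)
        if w.min() > 0:
            return self.V
        w = np.clip(w, floor, None)
        return q @ np.diag(w) @ q.T


def _align_alleles(ref: pd.DataFrame, other: pd.DataFrame) -> pd.DataFrame:
    """Align ``other`` to ``ref`` allele orientation on shared SNPs.

    Swapped a1/a2 flips the beta sign; mismatched or strand-ambiguous
    (A/T, C/G) variants are dropped.
    """
    merged = other.merge(
        ref[["SNP", "A1", "A2"]].rename(columns={"A1": "refA1", "A2": "refA2"}),
        on="SNP",
    )
    ambiguous = [
        (a1, a2) in AMBIGUOUS for a1, a2 in zip(merged["A1"], merged["A2"])
    ]
    same = (merged["A1"] == merged["refA1"]) & (merged["A2"] == merged["refA2"])
    swapped = (merged["A1"] == merged["refA2"]) & (merged["A2"] == merged["refA1"])
    keep = (same | swapped) & ~np.array(ambiguous)
    merged = merged[keep].copy()
    flip = swapped[keep]
    merged.loc[flip, "BETA"] = -merged.loc[flip, "BETA"]
    merged.loc[flip, ["A1", "A2"]] = merged.loc[flip, ["refA2", "refA1"]].to_numpy()
    return merged.drop(columns=["refA1", "refA2"])


def _weighted_block_fit(
    ell: np.ndarray, y: np.ndarray, w: np.ndarray, block_id: np.ndarray, n_blocks: int
):
    """Weighted regression of y on (1, ell) plus delete-one-block estimates.

    Returns (intercept, slope, per-block-deleted slopes).
    """
    x0 = np.ones_like(ell)
    # per-block accumulators of X'WX (2x2 symmetric) and X'Wy
    a00 = np.bincount(block_id, w * x0, minlength=n_blocks)
    a01 = np.bincount(block_id, w * ell, minlength=n_blocks)
    a11 = np.bincount(block_id, w * ell * ell, minlength=n_blocks)
    c0 = np.bincount(block_id, w * y, minlength=n_blocks)
    c1 = np.bincount(block_id, w * ell * y, minlength=n_blocks)
    A = np.array([[a00.sum(), a01.sum()], [a01.sum(), a11.sum()]])
    c = np.array([c0.sum(), c1.sum()])
    theta = np.linalg.solve(A, c)
    # delete-one-block slopes
    slopes = np.empty(n_blocks)
    for bidx in range(n_blocks):
        Ab = A - np.array([[a00[bidx], a01[bidx]], [a01[bidx], a11[bidx]]])
        cb = c - np.array([c0[bidx], c1[bidx]])
        slopes[bidx] = np.linalg.solve(Ab, cb)[1]
    return theta[0], theta[1], slopes


def ldsc_regression(
    sumstats: dict[str, pd.DataFrame] | list[pd.DataFrame],
    ldscores: pd.DataFrame,
    n_blocks: int = 200,
) -> GeneticCovariance:
    """Multivariate LDSC: estimate S and its jackknife sampling covariance V.

    SNPs are intersected across traits and allele-aligned to the first
    trait; strand-ambiguous variants are dropped.  Each (co)variance element
    comes from a weighted regression of ``z_d * z_e`` on LD score with free
    intercept; ``V`` is the delete-one-block jackknife covariance of the
    vech(S) estimates over ``n_blocks`` contiguous SNP blocks.
    """
    if isinstance(sumstats, dict):
        traits = list(sumstats.keys())
        frames = [sumstats[t] for t in traits]
    else:
        frames = list(sumstats)
        traits = [f"trait{i + 1}" for i in range(len(frames))]
    k = len(frames)

    ref = frames[0]
    aligned = [ref] + [_align_alleles(ref, f) for f in frames[1:]]
    shared = set(aligned[0]["SNP"])
    for f in aligned[1:]:
        shared &= set(f["SNP"])
    shared &= set(ldscores["SNP"])
    if len(shared) < 2 * n_blocks:
        raise ValueError(
            f"only {len(shared)} shared SNPs; need >= {2 * n_blocks} for "
            f"{n_blocks} jackknife blocks"
        )
    base = ref[ref["SNP"].isin(shared)][["SNP", "CHR", "POS"]].sort_values(
        ["CHR", "POS"]
    )
    order = base["SNP"].to_numpy()
    m = len(order)
    ell = (
        ldscores.set_index("SNP").loc[order, "L2"].to_numpy(dtype=float)
    )
    if np.allclose(ell, ell[0]):
        raise ValueError("all LD scores equal; regression slope unidentifiable")
    z = np.empty((m, k))
    n_eff = np.empty(k)
    for d, f in enumerate(aligned):
        sub = f.set_index("SNP").loc[order]
        z[:, d] = (sub["BETA"] / sub["SE"]).to_numpy(dtype=float)
        n_eff[d] = float(sub["N"].mean())

    block_id = np.minimum(
        (np.arange(m) * n_blocks) // m, n_blocks - 1
    )
    S = np.zeros((k, k))
    intercepts = np.zeros((k, k))
    pairs = vech_indices(k)
    jack = np.zeros((len(pairs), n_blocks))
    for p_idx, (i, j) in enumerate(pairs):
        y = z[:, i] * z[:, j]
        # first pass: 1/l weights; second pass adds heteroskedasticity term
        w = 1.0 / np.clip(ell, 1.0, None)
        icpt, slope, _ = _weighted_block_fit(ell, y, w, block_id, n_blocks)
        hij = max(min(slope * m / np.sqrt(n_eff[i] * n_eff[j]), 5.0), -5.0)
        pred_i = 1.0 + n_eff[i] * max(hij, 0.0) * ell / m
        pred_j = 1.0 + n_eff[j] * max(hij, 0.0) * ell / m
        w = 1.0 / (np.clip(ell, 1.0, None) * pred_i * pred_j)
        icpt, slope, slopes_del = _weighted_block_fit(ell, y, w, block_id, n_blocks)
        conv = m / np.sqrt(n_eff[i] * n_eff[j])
        S[i, j] = S[j, i] = slope * conv
        intercepts[i, j] = intercepts[j, i] = icpt
        jack[p_idx] = slopes_del * conv
    # delete-one-block jackknife covariance
    jbar = jack.mean(axis=1)
    dev = jack - jbar[:, None]
    V = (n_blocks - 1) / n_blocks * (dev @ dev.T)
    gc = GeneticCovariance(S=S, V=V, intercepts=intercepts, traits=traits, n_snps=m)
    if np.linalg.eigvalsh((V + V.T) / 2).min() <= 0:
        gc.v_smoothed = True
        log.warning("sampling covariance V was indefinite; smoothing applied")
        gc.V = gc.smoothed_V()
    return gc
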