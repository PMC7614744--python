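"""Genotype / summary-statistic I/O and variant- and sample-level QC.

The central container is :class:`GenotypePanel`, an individuals x variants
dosage matrix (counts of the effect allele ``a1``; ``-1`` encodes missing)
with PLINK-style variant metadata.  GWAS summary statistics are plain
:class:`pandas.DataFrame` objects with the canonical columns
``CHR POS SNP A1 A2 BETA SE P N [INFO] [FREQ]``.

QC follows the conventional PLINK workflow: per-variant filters (MAF,
missingness, Hardy-Weinberg exact test), LD pruning, principal-component
ancestry outlier removal, and identity-by-descent relatedness filtering.
All coordinates are 1-based inclusive (bim convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

log = logging.getLogger(__name__)

MISSING = -1

#: synonyms accepted when reading summary statistics
DEFAULT_COLUMN_MAP = {
    "CHR": ["CHR", "CHROM", "CHROMOSOME", "#CHROM"],
    "POS": ["POS", "BP", "POSITION"],
    "SNP": ["SNP", "ID", "RSID", "MARKERNAME"],
    "A1": ["A1", "EFFECT_ALLELE", "EA", "ALT"],
    "A2": ["A2", "OTHER_ALLELE", "OA", "REF"],
    "BETA": ["BETA", "B", "EFFECT", "OR", "LOG_ODDS"],
    "SE": ["SE", "STDERR", "STDERRLOGOR"],
    "P": ["P", "PVAL", "P_VALUE", "PVALUE"],
    "N": ["N", "NEFF", "N_TOTAL", "SAMPLESIZE"],
    "INFO": ["INFO", "IMPINFO", "R2HAT"],
    "FREQ": ["FREQ", "EAF", "FRQ", "MAF_FREQ", "AF"],
}

SUMSTATS_COLUMNS = ["CHR", "POS", "SNP", "A1", "A2", "BETA", "SE", "P", "N"]


@dataclass
class GenotypePanel:
    """Individuals x variants dosage panel.

    Attributes
    ----------
    samples : ndarray of str
        Unique sample identifiers.
    variants : DataFrame
        One row per variant with columns ``chrom, pos, id, a1, a2``;
        positions 1-based, non-decreasing within chromosome.
    dosages : ndarray (n_samples, n_variants), int8
        Count of ``a1`` per individual in {0, 1, 2}; -1 = missing.
    """

    samples: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        ids = self.variants["id"]
        if ids.duplicated().any():
            raise ValueError("duplicate variant ids")
        for _, sub in self.variants.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise ValueError("positions must be non-decreasing within chromosome")
        if (self.variants["a1"] == self.variants["a2"]).any():
            raise ValueError("a1 must differ from a2")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def freqs(self) -> np.ndarray:
        """Per-variant a1 allele frequency over non-missing genotypes."""
        d = self.dosages.astype(float)
        d[d == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def sample_missingness(self) -> np.ndarray:
        return self.missing_mask().mean(axis=1)

    def variant_missingness(self) -> np.ndarray:
        return self.missing_mask().mean(axis=0)

    def genotype_counts(self) -> np.ndarray:
        """(n_variants, 3) counts of dosage 2 (hom a1), 1 (het), 0 (hom a2)."""
        out = np.empty((self.n_variants, 3), dtype=int)
        out[:, 0] = (self.dosages == 2).sum(axis=0)
        out[:, 1] = (self.dosages == 1).sum(axis=0)
        out[:, 2] = (self.dosages == 0).sum(axis=0)
        return out

    def standardized(self) -> np.ndarray:
        """Mean-imputed, unit-variance standardized dosages (float64)."""
        d = self.dosages.astype(float)
        d[d == MISSING] = np.nan
        mean = np.nanmean(d, axis=0)
        d = np.where(np.isnan(d), mean, d)
        sd = d.std(axis=0)
        sd[sd == 0] = 1.0
        return (d - mean) / sd

    def subset_variants(self, mask_or_ids) -> "GenotypePanel":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            wanted = set(mask_or_ids)
            idx = np.flatnonzero(self.variants["id"].isin(wanted).to_numpy())
        return GenotypePanel(
            self.samples,
            self.variants.iloc[idx].reset_index(drop=True),
            self.dosages[:, idx],
        )

    def subset_samples(self, keep_ids) -> "GenotypePanel":
        wanted = set(keep_ids)
        mask = np.array([s in wanted for s in self.samples])
        return GenotypePanel(
            self.samples[mask], self.variants.copy(), self.dosages[mask]
        )


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit genotype codes in SNP-major bed files, LSB first within a byte:
# 00 = hom a1 (dosage 2), 01 = missing, 10 = het, 11 = hom a2 (dosage 0)
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write the panel as PLINK bed/bim/fam (bit-exact SNP-major bed)."""
    prefix = Path(prefix)
    n = panel.n_samples
    bim = pd.DataFrame(
        {
            "chrom": panel.variants["chrom"],
            "id": panel.variants["id"],
            "cm": 0,
            "pos": panel.variants["pos"],
            "a1": panel.variants["a1"],
            "a2": panel.variants["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": panel.samples,
            "iid": panel.samples,
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        codes = np.empty(n, dtype=np.uint8)
        for j in range(panel.n_variants):
            col = panel.dosages[:, j]
            codes[col == 2] = 0b00
            codes[col == MISSING] = 0b01
            codes[col == 1] = 0b10
            codes[col == 0] = 0b11
            padded = np.zeros(n_bytes * 4, dtype=np.uint8)
            padded[:n] = codes
            packed = (
                padded[0::4]
                | (padded[1::4] << 2)
                | (padded[2::4] << 4)
                | (padded[3::4] << 6)
            )
            fh.write(packed.tobytes())


def read_plink(prefix: str | Path) -> GenotypePanel:
    """Read PLINK bed/bim/fam into a :class:`GenotypePanel`."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"iid": str},
    )
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(
            "not a SNP-major PLINK bed file (magic bytes "
            f"{raw[:3].hex()} != {_BED_MAGIC.hex()})"
        )
    n, m = len(fam), len(bim)
    n_bytes = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != n_bytes * m:
        raise ValueError(
            f"bed payload has {payload.size} bytes; expected {n_bytes * m} "
            f"for {n} samples x {m} variants"
        )
    dosages = np.empty((n, m), dtype=np.int8)
    if m:
        mat = payload.reshape(m, n_bytes)
        codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
        codes[:, 0::4] = mat & 0b11
        codes[:, 1::4] = (mat >> 2) & 0b11
        codes[:, 2::4] = (mat >> 4) & 0b11
        codes[:, 3::4] = (mat >> 6) & 0b11
        dosages = _CODE_TO_DOSAGE[codes[:, :n]].T
    variants = bim[["chrom", "pos", "id", "a1", "a2"]].copy()
    return GenotypePanel(fam["iid"].to_numpy(dtype=object), variants, dosages)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------


def read_sumstats(
    path: str | Path, column_map: dict[str, list[str]] | None = None
) -> pd.DataFrame:
    """Read tab-delimited GWAS summary statistics with header synonyms.

    ``OR`` columns are converted to ``BETA = ln(OR)``; rows with unparseable
    numerics are dropped (counted in the log), as are second and later
    occurrences of a duplicated variant id.
    """
    cmap = column_map or DEFAULT_COLUMN_MAP
    df = pd.read_csv(path, sep="\t")
    upper = {c.upper(): c for c in df.columns}
    resolved: dict[str, str] = {}
    for canon, synonyms in cmap.items():
        for syn in synonyms:
            if syn.upper() in upper:
                resolved[canon] = upper[syn.upper()]
                break
    required = [c for c in SUMSTATS_COLUMNS]
    missing = [c for c in required if c not in resolved]
    if missing:
        raise ValueError(f"missing required summary-statistic columns: {missing}")

    out = pd.DataFrame()
    is_or = resolved["BETA"].upper() == "OR"
    for canon, src in resolved.items():
        out[canon] = df[src]
    for col in ["POS", "BETA", "SE", "P", "N"] + [
        c for c in ("INFO", "FREQ") if c in out
    ]:
        out[col] = pd.to_numeric(out[col], errors="coerce")
    n_in = len(out)
    out = out.dropna(subset=[c for c in ["POS", "BETA", "SE", "P", "N"]])
    n_bad = n_in - len(out)
    if n_bad:
        log.warning("dropped %d rows with unparseable numeric fields", n_bad)
    if is_or:
        out["BETA"] = np.log(out["BETA"])
    dup = out["SNP"].duplicated()
    if dup.any():
        log.warning("dropped %d duplicated variant ids (kept first)", int(dup.sum()))
        out = out[~dup]
    out["CHR"] = out["CHR"].astype(str)
    out["SNP"] = out["SNP"].astype(str)
    out["POS"] = out["POS"].astype(int)
    return out.reset_index(drop=True)


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in SUMSTATS_COLUMNS + ["INFO", "FREQ"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Conditional on the observed allele counts, heterozygote counts are
    distributed with probability proportional to
    ``n! / (nAA! nAa! naa!) * 2**nAa``; the p-value sums the probabilities
    of all configurations no more likely than the observed one.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_hom1 + n_het  # count of the rarer-or-not allele 1
    n_b = 2 * n_hom2 + n_het
    n_minor = min(n_a, n_b)
    # feasible heterozygote counts share parity with the minor-allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    # unnormalized log-probabilities via gammaln
    hom1 = (min(n_a, n_b) - hets) // 2
    hom2 = n - hets - hom1
    logp = (
        hets * np.log(2.0)
        - gammaln(hom1 + 1)
        - gammaln(hets + 1)
        - gammaln(hom2 + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = n_het
    p_obs = probs[hets == obs]
    if p_obs.size == 0:  # inconsistent counts cannot occur from valid input
        return 1.0
    p = probs[probs <= p_obs[0] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_pvalues(panel: GenotypePanel) -> np.ndarray:
    counts = panel.genotype_counts()
    return np.array([hwe_exact_test(*row) for row in counts])


# ---------------------------------------------------------------------------
# Variant-level QC
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    """Removal counts attributed to the first failing criterion, in order."""

    n_input: int = 0
    n_output: int = 0
    removed: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input)]
        rows += [(f"removed_{k}", v) for k, v in self.removed.items()]
        rows.append(("output", self.n_output))
        return pd.DataFrame(rows, columns=["item", "count"])


def variant_qc_filter(
    obj,
    maf_min: float = 0.01,
    miss_max: float = 0.05,
    hwe_min: float = 1e-5,
    info_min: float = 0.9,
):
    """Apply variant-level QC filters.

    For a :class:`GenotypePanel`: retain variants with minor allele frequency
    >= ``maf_min``, missingness <= ``miss_max`` and Hardy-Weinberg exact p
    >= ``hwe_min``.  For summary statistics (DataFrame): retain variants with
    MAF >= ``maf_min`` (from FREQ, if present) and INFO >= ``info_min``.
    Returns ``(filtered, QCReport)``; removals are attributed to the first
    failing criterion in the order stated.
    """
    if not (0 <= maf_min <= 0.5 and 0 <= miss_max <= 1 and 0 <= hwe_min <= 1):
        raise ValueError("QC thresholds out of range")
    report = QCReport()
    if isinstance(obj, GenotypePanel):
        freq = obj.freqs()
        maf = np.minimum(freq, 1 - freq)
        miss = obj.variant_missingness()
        hwe = hwe_pvalues(obj)
        report.n_input = obj.n_variants
        fail_maf = maf < maf_min
        fail_miss = (~fail_maf) & (miss > miss_max)
        fail_hwe = (~fail_maf) & (~fail_miss) & (hwe < hwe_min)
        keep = ~(fail_maf | fail_miss | fail_hwe)
        report.removed = {
            "maf": int(fail_maf.sum()),
            "missingness": int(fail_miss.sum()),
            "hwe": int(fail_hwe.sum()),
        }
        out = obj.subset_variants(keep)
        report.n_output = out.n_variants
        return out, report
    df = obj
    report.n_input = len(df)
    if "FREQ" in df.columns:
        maf = np.minimum(df["FREQ"], 1 - df["FREQ"]).to_numpy()
        fail_maf = maf < maf_min
    else:
        fail_maf = np.zeros(len(df), dtype=bool)
    if "INFO" in df.columns:
        fail_info = (~fail_maf) & (df["INFO"].to_numpy() < info_min)
    else:
        fail_info = np.zeros(len(df), dtype=bool)
    keep = ~(fail_maf | fail_info)
    report.removed = {"maf": int(fail_maf.sum()), "info": int(fail_info.sum())}
    out = df[keep].reset_index(drop=True)
    report.n_output = len(out)
    return out, report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def _pairwise_r2(panel: GenotypePanel, i: int, j: int) -> float:
    """Squared dosage correlation on pairwise-complete observations."""
    a = panel.dosages[:, i].astype(float)
    b = panel.dosages[:, j].astype(float)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_prune(
    panel: GenotypePanel,
    window_kb: float = 50,
    step_kb: float = 5,
    r2_max: float = 0.5,
) -> list[str]:
    """Greedy left-to-right LD pruning; returns retained variant ids.

    Scanning variants in position order, a variant is dropped when its
    squared dosage correlation with any already-retained variant closer than
    ``window_kb`` exceeds ``r2_max`` (i.e., of an offending pair the
    later-position member is removed).  ``step_kb`` is accepted for interface
    compatibility with the sliding-window formulation; the greedy scan
    visits every variant so the result does not depend on it.
    """
    window_bp = window_kb * 1000
    ids = panel.variants["id"].to_numpy()
    chroms = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos"].to_numpy()
    kept: list[int] = []
    for j in range(panel.n_variants):
        ok = True
        for i in reversed(kept):
            if chroms[i] != chroms[j]:
                break
            if pos[j] - pos[i] > window_bp:
                break
            if _pairwise_r2(panel, i, j) > r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
    return [str(x) for x in ids[kept]]


# ---------------------------------------------------------------------------
# PCA ancestry outliers
# ---------------------------------------------------------------------------


def pca_ancestry_filter(
    panel: GenotypePanel, n_pcs: int = 4, sd_limit: float = 4.0
):
    """Remove samples beyond ``sd_limit`` standard deviations on any of the
    first ``n_pcs`` principal components of the standardized dosage matrix.

    A single pass (no iterative re-computation).  Returns
    ``(retained_sample_ids, pc_coordinates DataFrame)`` where coordinates are
    for all input samples.
    """
    if n_pcs > min(panel.n_samples, panel.n_variants):
        raise ValueError("n_pcs exceeds matrix rank bound")
    x = panel.standardized()
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    pcs = u[:, :n_pcs] * s[:n_pcs]
    z = (pcs - pcs.mean(axis=0)) / pcs.std(axis=0, ddof=1)
    outlier = (np.abs(z) > sd_limit).any(axis=1)
    coords = pd.DataFrame(
        pcs, index=panel.samples, columns=[f"PC{i+1}" for i in range(n_pcs)]
    )
    retained = [s_ for s_, bad in zip(panel.samples, outlier) if not bad]
    return retained, coords


# ---------------------------------------------------------------------------
# IBD relatedness
# ---------------------------------------------------------------------------


def ibd_pi_hat(panel: GenotypePanel, pair: tuple[int, int]) -> float:
    """PLINK-style method-of-moments pi-hat for one sample pair.

    Observed identity-by-state counts are converted to IBD-state
    probabilities via the expected IBS sharing given allele frequencies,
    using the unbiased product-moment estimators (falling-factorial ratios
    of allele counts, as in PLINK) so small reference samples do not bias
    pi-hat upward: ``P(IBD0) = N_IBS0 / E[IBS0|IBD0]`` etc., then
    ``pi_hat = P(IBD1)/2 + P(IBD2)`` (clipped to [0, 1]).
    """
    i, j = pair
    a = panel.dosages.astype(float)[i]
    b = panel.dosages.astype(float)[j]
    d = panel.dosages.astype(float)
    d[d == MISSING] = np.nan
    x_cnt = np.nansum(d, axis=0)  # allele-1 count
    t_cnt = 2.0 * np.sum(~np.isnan(d), axis=0)  # total allele count
    ok = (
        (a != MISSING)
        & (b != MISSING)
        & (x_cnt > 0)
        & (x_cnt < t_cnt)
        & (t_cnt >= 4)
    )
    a, b = a[ok], b[ok]
    x, t = x_cnt[ok], t_cnt[ok]
    y = t - x
    ibs = 2 - np.abs(a - b)
    n0 = float((ibs == 0).sum())
    n1 = float((ibs == 1).sum())
    m = len(x)
    if m == 0:
        return 0.0
    denom4 = t * (t - 1) * (t - 2) * (t - 3)
    p2q2 = x * (x - 1) * y * (y - 1) / denom4
    p3q = x * (x - 1) * (x - 2) * y / denom4
    pq3 = x * y * (y - 1) * (y - 2) / denom4
    pq = x * y / (t * (t - 1))
    e0_ibd0 = float(np.sum(2 * p2q2))
    e1_ibd0 = float(np.sum(4 * p3q + 4 * pq3))
    e2_ibd0 = float(m) - e0_ibd0 - e1_ibd0
    e1_ibd1 = float(np.sum(2 * pq))
    e2_ibd1 = float(m) - e1_ibd1
    n2 = float(m) - n0 - n1
    p0 = n0 / e0_ibd0 if e0_ibd0 > 0 else 0.0
    p1 = (n1 - p0 * e1_ibd0) / e1_ibd1 if e1_ibd1 > 0 else 0.0
    p2 = (n2 - p0 * e2_ibd0 - p1 * e2_ibd1) / m
    p0, p1, p2 = max(p0, 0.0), max(p1, 0.0), max(p2, 0.0)
    total = p0 + p1 + p2
    if total > 0:
        p0, p1, p2 = p0 / total, p1 / total, p2 / total
    return float(min(max(0.5 * p1 + p2, 0.0), 1.0))


def ibd_filter(panel: GenotypePanel, pi_hat_max: float = 0.125) -> list[str]:
    """Greedy relatedness filter; returns retained sample ids.

    For every pair with pi-hat above the cutoff the member with the higher
    genotype missingness is removed (ties: the later sample id), repeating
    until no offending pair remains.
    """
    if panel.n_samples < 2:
        raise ValueError("need at least two samples")
    n = panel.n_samples
    miss = panel.sample_missingness()
    pihat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pihat[i, j] = pihat[j, i] = ibd_pi_hat(panel, (i, j))
    alive = np.ones(n, dtype=bool)
    while True:
        worst = None
        for i in range(n):
            if not alive[i]:
                continue
            for j in range(i + 1, n):
                if alive[j] and pihat[i, j] > pi_hat_max:
                    if worst is None or pihat[i, j] > worst[0]:
                        worst = (pihat[i, j], i, j)
        if worst is None:
            break
        _, i, j = worst
        if miss[i] > miss[j]:
            drop = i
        elif miss[j] > miss[i]:
            drop = j
        else:
            drop = j if panel.samples[j] > panel.samples[i] else i
        alive[drop] = False
    return [s for s, a in zip(panel.samples, alive) if a]
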