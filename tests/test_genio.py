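"""PLINK I/O, summary-statistic reading, and the QC filter chain."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from devpgs import genio
from devpgs.config import SimulationConfig
from devpgs.genio import (
    GenotypePanel,
    hwe_exact_test,
    ibd_filter,
    ibd_pi_hat,
    ld_prune,
    pca_ancestry_filter,
    read_plink,
    read_sumstats,
    variant_qc_filter,
    write_plink,
)
from devpgs.synthdata import simulate_genotypes

from conftest import make_panel


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------


class TestPlinkIO:
    def test_bed_payload_bytes_hand_encoded(self, tmp_path):
        """2 individuals x 1 SNP with dosages (0, 2): per the 2-bit code,
        sample1 = 11 (hom a2), sample2 = 00 (hom a1) -> byte 0b00000011."""
        panel = make_panel([[0], [2]])
        write_plink(panel, tmp_path / "toy")
        raw = (tmp_path / "toy.bed").read_bytes()
        assert raw[:3] == bytes([0x6C, 0x1B, 0x01])
        assert raw[3:] == bytes([0b00000011])

    def test_empty_variant_list(self, tmp_path):
        panel = make_panel(np.zeros((3, 0), dtype=np.int8))
        write_plink(panel, tmp_path / "empty")
        assert (tmp_path / "empty.bed").read_bytes() == bytes([0x6C, 0x1B, 0x01])
        back = read_plink(tmp_path / "empty")
        assert back.n_variants == 0 and back.n_samples == 3

    def test_roundtrip_random_panel_with_missing(self, tmp_path):
        rng = np.random.default_rng(0)
        dos = rng.integers(0, 3, size=(100, 100)).astype(np.int8)
        dos[rng.random((100, 100)) < 0.05] = genio.MISSING
        panel = make_panel(dos)
        write_plink(panel, tmp_path / "p")
        back = read_plink(tmp_path / "p")
        np.testing.assert_array_equal(back.dosages, panel.dosages)
        assert list(back.samples) == list(panel.samples)
        pd.testing.assert_frame_equal(
            back.variants.astype({"pos": int}), panel.variants.astype({"pos": int})
        )

    def test_bad_magic_rejected(self, tmp_path):
        panel = make_panel([[0, 1], [2, 1]])
        write_plink(panel, tmp_path / "x")
        raw = (tmp_path / "x.bed").read_bytes()
        (tmp_path / "x.bed").write_bytes(b"\x00\x00\x01" + raw[3:])
        with pytest.raises(ValueError, match="magic"):
            read_plink(tmp_path / "x")

    def test_payload_size_mismatch_rejected(self, tmp_path):
        panel = make_panel([[0, 1], [2, 1]])
        write_plink(panel, tmp_path / "y")
        raw = (tmp_path / "y.bed").read_bytes()
        (tmp_path / "y.bed").write_bytes(raw + b"\x00")
        with pytest.raises(ValueError, match="payload"):
            read_plink(tmp_path / "y")


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


class TestReadSumstats:
    def _write(self, tmp_path, text):
        f = tmp_path / "ss.tsv"
        f.write_text(text)
        return f

    def test_or_converted_to_log_scale(self, tmp_path):
        f = self._write(
            tmp_path,
            "CHR\tPOS\tSNP\tA1\tA2\tOR\tSE\tP\tN\n"
            "1\t100\trs1\tA\tG\t1.0\t0.1\t0.5\t1000\n"
            "1\t200\trs2\tA\tG\t2.0\t0.1\t0.01\t1000\n",
        )
        df = read_sumstats(f)
        assert df.loc[0, "BETA"] == 0.0
        assert abs(df.loc[1, "BETA"] - 0.6931) < 1e-4

    def test_duplicate_id_second_dropped(self, tmp_path):
        f = self._write(
            tmp_path,
            "CHR\tPOS\tSNP\tA1\tA2\tBETA\tSE\tP\tN\n"
            "1\t100\trs1\tA\tG\t0.1\t0.1\t0.5\t1000\n"
            "1\t200\trs1\tA\tG\t0.9\t0.1\t0.5\t1000\n",
        )
        df = read_sumstats(f)
        assert len(df) == 1 and df.loc[0, "BETA"] == 0.1

    def test_unparseable_rows_dropped_and_synonyms(self, tmp_path):
        f = self._write(
            tmp_path,
            "CHROM\tBP\tRSID\tEA\tOA\tB\tSTDERR\tPVAL\tNEFF\n"
            "1\t100\trs1\tA\tG\t0.1\t0.1\t0.5\t1000\n"
            "1\t200\trs2\tA\tG\tNA\t0.1\t0.5\t1000\n",
        )
        df = read_sumstats(f)
        assert len(df) == 1

    def test_missing_required_column_named(self, tmp_path):
        f = self._write(tmp_path, "CHR\tPOS\tSNP\tA1\tA2\tBETA\tSE\tP\n1\t1\ta\tA\tG\t0\t1\t1\n")
        with pytest.raises(ValueError, match="N"):
            read_sumstats(f)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_enumeration_oracle(n_hom1, n_het, n_hom2):
    """Full enumeration over feasible heterozygote counts with weights
    n! / (nAA! nAa! naa!) * 2**nAa, conditioned on the allele counts."""
    n = n_hom1 + n_het + n_hom2
    na = 2 * n_hom1 + n_het
    n_minor = min(na, 2 * n - na)
    hets = list(range(n_minor % 2, n_minor + 1, 2))
    weights = []
    for h in hets:
        h1 = (n_minor - h) // 2
        h2 = n - h - h1
        logw = h * np.log(2) - gammaln(h1 + 1) - gammaln(h + 1) - gammaln(h2 + 1)
        weights.append(np.exp(logw))
    weights = np.array(weights)
    probs = weights / weights.sum()
    p_obs = probs[hets.index(n_het)]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


class TestHWE:
    def test_two_hom_one_each(self):
        """(1, 0, 1): configurations {(1,0,1), (0,2,0)} with weights 2 and 4
        give p = 2/6 = 1/3."""
        assert abs(hwe_exact_test(1, 0, 1) - 1 / 3) < 1e-12

    def test_monomorphic_p_one(self):
        assert hwe_exact_test(7, 0, 0) == 1.0

    @pytest.mark.parametrize(
        "counts",
        [(1, 0, 1), (3, 4, 3), (10, 5, 2), (0, 10, 0), (2, 2, 2), (50, 20, 5)],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert abs(hwe_exact_test(*counts) - hwe_enumeration_oracle(*counts)) < 1e-10

    def test_heterozygote_excess_monotone(self):
        """At fixed allele counts, p decreases as the het count moves away
        from its modal value toward complete heterozygosity."""
        ps = [hwe_exact_test((20 - h) // 2, h, (20 - h) // 2) for h in (10, 14, 18)]
        assert ps[0] >= ps[1] >= ps[2]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 0, 1)


# ---------------------------------------------------------------------------
# variant QC
# ---------------------------------------------------------------------------


class TestVariantQC:
    def test_maf_boundary(self):
        rng = np.random.default_rng(1)
        n = 2000
        freq_low = rng.binomial(2, 0.009, n)  # MAF ~0.009 -> removed
        freq_ok = rng.binomial(2, 0.011, n)  # ~0.011 -> retained
        common = rng.binomial(2, 0.3, (n, 3))
        panel = make_panel(np.column_stack([freq_low, freq_ok, common]))
        out, report = variant_qc_filter(panel)
        kept = set(out.variants["id"])
        assert "v1" not in kept and "v2" in kept

    def test_all_pass_reports_zeros(self):
        rng = np.random.default_rng(2)
        panel = make_panel(rng.binomial(2, 0.3, (500, 6)))
        out, report = variant_qc_filter(panel)
        assert out.n_variants == 6
        assert all(v == 0 for v in report.removed.values())

    def test_one_violator_per_criterion_attributed(self):
        rng = np.random.default_rng(3)
        n = 1000
        cols, names = [], []
        for _ in range(7):
            cols.append(rng.binomial(2, 0.3, n))
        bad_maf = rng.binomial(2, 0.002, n)
        bad_miss = rng.binomial(2, 0.3, n)
        bad_miss[: int(0.2 * n)] = genio.MISSING
        bad_hwe = np.ones(n, dtype=np.int8)  # all het: extreme HWE violation
        panel = make_panel(
            np.column_stack(cols + [bad_maf, bad_miss, bad_hwe]).astype(np.int8)
        )
        out, report = variant_qc_filter(panel)
        assert report.removed == {"maf": 1, "missingness": 1, "hwe": 1}
        assert out.n_variants == 7
        assert report.n_input - report.n_output == sum(report.removed.values())

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        dos = rng.binomial(2, rng.uniform(0.002, 0.4, 20), (800, 20)).astype(np.int8)
        panel = make_panel(dos)
        once, _ = variant_qc_filter(panel)
        twice, rep2 = variant_qc_filter(once)
        assert list(twice.variants["id"]) == list(once.variants["id"])
        assert all(v == 0 for v in rep2.removed.values())

    def test_sumstats_info_filter(self):
        panel = make_panel(np.zeros((2, 3), dtype=np.int8) + 1)
        from conftest import make_sumstats

        ss = make_sumstats(panel, [0.1, 0.1, 0.1], freq=np.array([0.3, 0.3, 0.3]))
        ss["INFO"] = [0.95, 0.85, 0.99]
        out, report = variant_qc_filter(ss)
        assert list(out["SNP"]) == ["v1", "v3"]
        assert report.removed["info"] == 1


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def prune_oracle(panel, window_bp, r2_max):
    """Independent brute-force greedy scan."""
    kept = []
    d = panel.dosages.astype(float)
    pos = panel.variants["pos"].to_numpy()
    for j in range(panel.n_variants):
        ok = True
        for i in kept:
            if abs(pos[j] - pos[i]) <= window_bp:
                r = np.corrcoef(d[:, i], d[:, j])[0, 1]
                if r * r > r2_max:
                    ok = False
                    break
        if ok:
            kept.append(j)
    return [panel.variants["id"].iloc[j] for j in kept]


class TestLDPrune:
    def _correlated_pair(self, r_target=0.9, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.binomial(1, 0.5, (n, 2)).sum(axis=1)
        flip = rng.random(n) < (1 - r_target) / 2
        b = a.copy()
        b[flip] = rng.integers(0, 3, flip.sum())
        return a, b

    def test_high_ld_pair_one_removed(self):
        a, b = self._correlated_pair()
        panel = make_panel(np.column_stack([a, b]), pos=[1000, 2000])
        kept = ld_prune(panel)
        assert kept == ["v1"]

    def test_independent_snps_all_retained(self):
        rng = np.random.default_rng(5)
        panel = make_panel(rng.binomial(2, 0.4, (2000, 8)))
        assert len(ld_prune(panel)) == 8

    def test_matches_bruteforce_oracle(self):
        cfg = SimulationConfig(
            n_individuals=300, n_snps=10, n_genes=5, ld_block_size=5,
            ld_rho=0.9, snp_spacing_bp=10_000, seed=9,
        )
        panel = simulate_genotypes(cfg)
        assert ld_prune(panel) == prune_oracle(panel, 50_000, 0.5)

    def test_idempotent(self):
        cfg = SimulationConfig(
            n_individuals=300, n_snps=30, n_genes=5, ld_block_size=6,
            ld_rho=0.85, snp_spacing_bp=5_000, seed=10,
        )
        panel = simulate_genotypes(cfg)
        kept = ld_prune(panel)
        again = ld_prune(panel.subset_variants(kept))
        assert again == kept


# ---------------------------------------------------------------------------
# PCA ancestry filter
# ---------------------------------------------------------------------------


class TestPCAFilter:
    def test_homogeneous_panel_few_removals(self):
        removed = 0
        for seed in range(10):
            cfg = SimulationConfig(
                n_individuals=200, n_snps=100, n_genes=5, ld_rho=0.0, seed=seed
            )
            panel = simulate_genotypes(cfg)
            kept, _ = pca_ancestry_filter(panel)
            removed += panel.n_samples - len(kept)
        assert removed <= 2  # 4-sd outliers are ~6e-5 per draw

    def test_planted_outlier_removed(self):
        rng = np.random.default_rng(11)
        dos = rng.binomial(2, 0.5, (100, 200)).astype(np.int8)
        dos[0] = 2  # one individual homozygous everywhere: extreme on PC1
        panel = make_panel(dos)
        kept, coords = pca_ancestry_filter(panel)
        assert "S1" not in kept

    def test_pc_orthogonality(self):
        rng = np.random.default_rng(12)
        panel = make_panel(rng.binomial(2, 0.4, (80, 120)))
        _, coords = pca_ancestry_filter(panel)
        x = coords.to_numpy()
        x = x - x.mean(axis=0)
        gram = x.T @ x
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_too_many_pcs_rejected(self):
        panel = make_panel(np.ones((3, 2), dtype=np.int8))
        with pytest.raises(ValueError):
            pca_ancestry_filter(panel, n_pcs=5)


# ---------------------------------------------------------------------------
# IBD filter
# ---------------------------------------------------------------------------


class TestIBD:
    def _family_panel(self, n_unrelated=20, m=4000, seed=13):
        """Unrelated individuals plus one full-sib pair drawn from shared
        parents."""
        rng = np.random.default_rng(seed)
        freq = rng.uniform(0.2, 0.5, m)
        geno = rng.binomial(2, freq, (n_unrelated, m))
        # parents, then two children by Mendelian transmission
        def child(pa, ma):
            ha = np.where(pa == 1, rng.integers(0, 2, m), pa // 2)
            hb = np.where(ma == 1, rng.integers(0, 2, m), ma // 2)
            return ha + hb

        pa = rng.binomial(2, freq)
        ma = rng.binomial(2, freq)
        sibs = np.vstack([child(pa, ma), child(pa, ma)])
        return make_panel(np.vstack([geno, sibs]).astype(np.int8))

    def test_sib_pair_pihat_near_half_one_removed(self):
        panel = self._family_panel()
        n = panel.n_samples
        pihat = ibd_pi_hat(panel, (n - 2, n - 1))
        assert 0.35 < pihat < 0.65
        kept = ibd_filter(panel)
        assert len(kept) == n - 1

    def test_unrelated_panel_none_removed(self):
        """pi-hat needs many (pruned) SNPs to concentrate; at a few thousand
        markers no unrelated pair should cross the 0.125 cutoff."""
        removals = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            freq = rng.uniform(0.2, 0.5, 4000)
            panel = make_panel(rng.binomial(2, freq, (15, 4000)).astype(np.int8))
            removals += 15 - len(ibd_filter(panel))
        assert removals == 0

    def test_toy_pair_matches_mom_algebra(self):
        """Toy pair checked against the closed-form IBS -> IBD
        method-of-moments algebra (unbiased allele-count moments) computed
        independently in the test."""
        rng = np.random.default_rng(42)
        dos = rng.integers(0, 3, size=(6, 12)).astype(np.int8)
        panel = make_panel(dos)
        i, j = 0, 1
        x = dos.sum(axis=0).astype(float)
        t = np.full(dos.shape[1], 2.0 * dos.shape[0])
        ok = (x > 0) & (x < t)
        x, t = x[ok], t[ok]
        y = t - x
        a, b = dos[i, ok].astype(float), dos[j, ok].astype(float)
        ibs = 2 - np.abs(a - b)
        n0, n1 = float((ibs == 0).sum()), float((ibs == 1).sum())
        m = len(x)
        n2 = m - n0 - n1
        den = t * (t - 1) * (t - 2) * (t - 3)
        e0 = float(np.sum(2 * x * (x - 1) * y * (y - 1) / den))
        e1_0 = float(
            np.sum(4 * x * (x - 1) * (x - 2) * y / den)
            + np.sum(4 * x * y * (y - 1) * (y - 2) / den)
        )
        e2_0 = m - e0 - e1_0
        e1_1 = float(np.sum(2 * x * y / (t * (t - 1))))
        e2_1 = m - e1_1
        p0 = n0 / e0
        p1 = (n1 - p0 * e1_0) / e1_1
        p2 = (n2 - p0 * e2_0 - p1 * e2_1) / m
        p0, p1, p2 = max(p0, 0), max(p1, 0), max(p2, 0)
        tot = p0 + p1 + p2
        expected = min(max((0.5 * p1 + p2) / tot, 0.0), 1.0)
        assert abs(ibd_pi_hat(panel, (i, j)) - expected) < 1e-10
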