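import numpy as np
import pandas as pd
import pytest

from devpgs.config import SimulationConfig
from devpgs.genio import GenotypePanel


def make_panel(dosages, pos=None, chrom="1", a1=None, a2=None, ids=None):
    """Toy panel from an explicit dosage matrix (rows = samples)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    pos = list(pos) if pos is not None else [(j + 1) * 1000 for j in range(m)]
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "id": ids or [f"v{j + 1}" for j in range(m)],
            "a1": a1 or ["A"] * m,
            "a2": a2 or ["G"] * m,
        }
    )
    samples = np.array([f"S{i + 1}" for i in range(n)], dtype=object)
    return GenotypePanel(samples, variants, dosages)


def make_sumstats(panel, beta, se=None, p=None, n=50_000, freq=None):
    """Summary statistics aligned to a panel's variants."""
    m = panel.n_variants
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se if se is not None else np.ones(m), dtype=float)
    z = beta / se
    from scipy import stats

    p = np.asarray(
        p if p is not None else np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    )
    df = panel.variants[["chrom", "pos", "id", "a1", "a2"]].rename(
        columns={"chrom": "CHR", "pos": "POS", "id": "SNP", "a1": "A1", "a2": "A2"}
    )
    df["BETA"] = beta
    df["SE"] = se
    df["P"] = p
    df["N"] = n
    df["FREQ"] = freq if freq is not None else panel.freqs()
    return df


@pytest.fixture(scope="session")
def small_study():
    """One modest synthetic study reused by read-only tests."""
    from devpgs.synthdata import simulate_study

    cfg = SimulationConfig(
        n_individuals=400, n_snps=800, n_genes=80, seed=7
    )
    return simulate_study(cfg)
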