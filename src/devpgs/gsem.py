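"""Genomic structural equation modelling on a genetic covariance matrix.

Three estimators operate on the LDSC output ``(S, V)``:

* :func:`efa_promax` — exploratory minimum-residual factoring of the
  standardized S with oblique promax rotation (power 4) and a loading
  cutoff for factor definitions;
* :func:`cfa_wls` — confirmatory correlated-factors model fitted by
  diagonally-weighted least squares (weights 1/diag(V)), with a
  residual-based chi-square that uses the full sampling covariance V,
  CFI versus the independence model, SRMR and AIC;
* :func:`common_factor_gwas` — per-SNP regression of each latent factor on
  the SNP.  SNP-trait covariances (standardized betas) are projected onto
  the factor space through the fixed measurement model: with ``A = Lambda
  Phi``, the SNP's factor effects solve the weighted least-squares system
  ``cov(SNP, indicators) = A g`` with weights from the per-trait sampling
  variances, which reproduces the closed-form one-factor result
  ``g = b / lambda`` and vectorises over SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ldsc import GeneticCovariance, vech, vech_indices

log = logging.getLogger(__name__)

#: default three-correlated-factor model (indicator names -> factor)
DEFAULT_MODEL_SPEC: dict[str, list[str]] = {
    "NDV": ["ADHD", "ASD", "MDD", "TS"],
    "COMP": ["AN", "OCD", "TS"],
    "MP": ["BIP", "MDD", "SCZ"],
}


# ---------------------------------------------------------------------------
# Exploratory factor analysis
# ---------------------------------------------------------------------------


def _varimax(loadings: np.ndarray, tol: float = 1e-10, max_iter: int = 500):
    """Orthogonal varimax rotation; returns (rotated, rotation matrix)."""
    p, k = loadings.shape
    rot = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        lam = loadings @ rot
        u, s, vt = np.linalg.svd(
            loadings.T @ (lam**3 - lam @ np.diag((lam**2).sum(axis=0)) / p)
        )
        rot = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol:
            break
        var_old = var_new
    return loadings @ rot, rot


def _promax(loadings: np.ndarray, power: int = 4):
    """Oblique promax rotation (power 4) of a varimax solution.

    Returns (pattern loadings, factor correlation matrix).
    """
    x, rotmat = _varimax(loadings)
    # degenerate (near-zero) loadings: nothing to rotate obliquely
    if np.linalg.norm(x) < 1e-6 or np.linalg.matrix_rank(x) < x.shape[1]:
        return x, np.eye(x.shape[1])
    target = x * np.abs(x) ** (power - 1)
    u, *_ = np.linalg.lstsq(x, target, rcond=None)
    d = np.diag(np.linalg.inv(u.T @ u))
    u = u @ np.diag(np.sqrt(d))
    pattern = x @ u
    phi = np.linalg.inv(u.T @ u)
    # normalize to exact unit diagonal
    dd = np.sqrt(np.diag(phi))
    phi = phi / np.outer(dd, dd)
    return pattern, phi


def _minres_loadings(corr: np.ndarray, n_factors: int) -> np.ndarray:
    """Minimum-residual (ULS) factor extraction.

    Optimizes the uniquenesses so the discarded eigenvalues of the reduced
    correlation matrix are as small as possible, then takes loadings from
    the leading eigenpairs.
    """
    k = corr.shape[0]

    def objective(psi: np.ndarray) -> float:
        reduced = corr - np.diag(psi)
        w = np.linalg.eigvalsh(reduced)[::-1]
        return float(np.sum(w[n_factors:] ** 2))

    smc = 1.0 - 1.0 / np.diag(np.linalg.inv(corr))
    start = np.clip(1.0 - smc, 0.05, 0.95)
    res = optimize.minimize(
        objective,
        start,
        method="L-BFGS-B",
        bounds=[(0.005, 1.0)] * k,
    )
    reduced = corr - np.diag(res.x)
    w, v = np.linalg.eigh(reduced)
    idx = np.argsort(w)[::-1][:n_factors]
    lam = v[:, idx] * np.sqrt(np.clip(w[idx], 0, None))
    # sign convention: make each factor's largest loading positive
    for f in range(n_factors):
        if lam[np.argmax(np.abs(lam[:, f])), f] < 0:
            lam[:, f] = -lam[:, f]
    return lam


@dataclass
class FactorSolution:
    loadings: np.ndarray  # pattern loadings, indicators x factors
    phi: np.ndarray  # factor correlations
    communalities: np.ndarray
    variance_explained: float  # proportion of total (standardized) variance
    loading_cutoff: float
    masked_loadings: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        masked = self.loadings.copy()
        masked[np.abs(masked) < self.loading_cutoff] = 0.0
        self.masked_loadings = masked

    def factor_indicators(self, names: list[str]) -> dict[int, list[str]]:
        """Indicators defining each factor after the loading cutoff."""
        out: dict[int, list[str]] = {}
        for f in range(self.loadings.shape[1]):
            out[f] = [
                names[i]
                for i in range(len(names))
                if self.masked_loadings[i, f] != 0.0
            ]
        return out


def efa_promax(
    S: np.ndarray, n_factors: int = 3, loading_cutoff: float = 0.2
) -> FactorSolution:
    """Exploratory factor analysis of a genetic covariance matrix.

    S is standardized to correlation scale, factored by minimum residuals
    and obliquely rotated (promax, power 4); loadings below the cutoff in
    absolute value are masked from the factor definitions.
    """
    S = np.asarray(S, dtype=float)
    if not np.all(np.isfinite(S)):
        raise ValueError("S contains non-finite entries")
    k = S.shape[0]
    if n_factors >= k:
        raise ValueError("n_factors must be smaller than the number of traits")
    d = np.sqrt(np.diag(S))
    corr = S / np.outer(d, d)
    lam = _minres_loadings(corr, n_factors)
    if n_factors > 1:
        pattern, phi = _promax(lam)
    else:
        pattern, phi = lam, np.eye(1)
    comm = np.einsum("if,fg,ig->i", pattern, phi, pattern)
    return FactorSolution(
        loadings=pattern,
        phi=phi,
        communalities=comm,
        variance_explained=float(np.clip(comm.sum() / k, 0.0, 1.0)),
        loading_cutoff=loading_cutoff,
    )


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-factor Tucker congruence after greedy column matching (absolute
    value; columns of b are matched to columns of a)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    k = a.shape[1]
    cong = np.abs(
        (a.T @ b)
        / np.sqrt(np.outer((a**2).sum(axis=0), (b**2).sum(axis=0)))
    )
    out = np.empty(k)
    used: set[int] = set()
    for f in np.argsort(-cong.max(axis=1)):
        best = max(
            (c for c in range(k) if c not in used), key=lambda c: cong[f, c]
        )
        used.add(best)
        out[f] = cong[f, best]
    return out


# ---------------------------------------------------------------------------
# Confirmatory factor analysis (DWLS)
# ---------------------------------------------------------------------------


@dataclass
class CFAFit:
    params: pd.DataFrame  # name, estimate, se
    chi2: float
    df: int
    p: float
    aic: float
    cfi: float
    srmr: float
    implied: np.ndarray
    loadings: np.ndarray
    phi: np.ndarray
    resid_var: np.ndarray
    traits: list[str]
    factors: list[str]


class _CFAModel:
    """Correlated-factors measurement model with factor variances fixed at 1."""

    def __init__(self, traits: list[str], spec: dict[str, list[str]]):
        self.traits = traits
        self.factors = list(spec.keys())
        idx = {t: i for i, t in enumerate(traits)}
        self.edges = []  # (trait index, factor index)
        for f_i, f in enumerate(self.factors):
            indicators = spec[f]
            if len(set(indicators)) < 2:
                raise ValueError(
                    f"factor {f!r} has fewer than 2 indicators; not identified"
                )
            for t in indicators:
                if t not in idx:
                    raise ValueError(f"unknown indicator {t!r}")
                self.edges.append((idx[t], f_i))
        self.k = len(traits)
        self.nf = len(self.factors)
        self.n_phi = self.nf * (self.nf - 1) // 2
        self.n_free = len(self.edges) + self.n_phi + self.k

    def unpack(self, theta: np.ndarray):
        k, nf = self.k, self.nf
        lam = np.zeros((k, nf))
        for e, (t, f) in enumerate(self.edges):
            lam[t, f] = theta[e]
        phi = np.eye(nf)
        pos = len(self.edges)
        for j in range(nf):
            for i in range(j + 1, nf):
                phi[i, j] = phi[j, i] = theta[pos]
                pos += 1
        resid = theta[pos : pos + k]
        return lam, phi, resid

    def implied(self, theta: np.ndarray) -> np.ndarray:
        lam, phi, resid = self.unpack(theta)
        return lam @ phi @ lam.T + np.diag(resid)

    def start(self, S: np.ndarray) -> np.ndarray:
        scale = np.sqrt(max(float(np.diag(S).mean()), 1e-3))
        theta = np.concatenate(
            [
                np.full(len(self.edges), 0.3 * scale),
                np.full(self.n_phi, 0.2),
                np.clip(0.5 * np.diag(S), 1e-4, None),
            ]
        )
        return theta

    def bounds(self):
        return (
            [(-5.0, 5.0)] * len(self.edges)
            + [(-0.99, 0.99)] * self.n_phi
            + [(1e-8, 10.0)] * self.k
        )

    def param_names(self) -> list[str]:
        names = [
            f"{self.traits[t]}~{self.factors[f]}" for t, f in self.edges
        ]
        for j in range(self.nf):
            for i in range(j + 1, self.nf):
                names.append(f"{self.factors[i]}~~{self.factors[j]}")
        names += [f"resid_{t}" for t in self.traits]
        return names


def _numeric_jacobian(fun, theta: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    f0 = fun(theta)
    jac = np.empty((f0.size, theta.size))
    for i in range(theta.size):
        step = np.zeros_like(theta)
        step[i] = eps
        jac[:, i] = (fun(theta + step) - fun(theta - step)) / (2 * eps)
    return jac


def _fit_indices(
    s_obs: np.ndarray,
    V: np.ndarray,
    resid_fun,
    jac: np.ndarray,
    df: int,
    S: np.ndarray,
    implied: np.ndarray,
):
    """Residual-based chi-square using the full sampling covariance V, plus
    CFI (vs the zero-covariance independence model) and SRMR."""
    r = resid_fun
    if df <= 0:
        return 0.0, 1.0, 0.0
    vinv = np.linalg.pinv((V + V.T) / 2)
    u = vinv - vinv @ jac @ np.linalg.pinv(jac.T @ vinv @ jac) @ jac.T @ vinv
    chi2 = float(r @ u @ r)
    chi2 = max(chi2, 0.0)
    # independence model: free variances only, zero covariances
    k = S.shape[0]
    indep = np.diag(np.diag(S))
    r0 = s_obs - vech(indep)
    jac0 = np.zeros((len(s_obs), k))
    for col, (i, j) in enumerate(vech_indices(k)):
        if i == j:
            jac0[col, i] = 1.0
    u0 = vinv - vinv @ jac0 @ np.linalg.pinv(jac0.T @ vinv @ jac0) @ jac0.T @ vinv
    chi2_0 = float(r0 @ u0 @ r0)
    df0 = len(s_obs) - k
    num = max(chi2 - df, 0.0)
    den = max(chi2_0 - df0, num, 1e-12)
    cfi = 1.0 - num / den
    d = np.sqrt(np.diag(S))
    std_resid = (S - implied) / np.outer(d, d)
    srmr = float(np.sqrt(np.mean(vech(std_resid) ** 2)))
    return chi2, cfi, srmr


def cfa_wls(
    gc_or_S,
    V: np.ndarray | None = None,
    model_spec: dict[str, list[str]] | None = None,
    traits: list[str] | None = None,
) -> CFAFit:
    """Fit a correlated-factors CFA to (S, V) by diagonally-weighted LS.

    The discrepancy ``(s - sigma(theta))' diag(V)^-1 (s - sigma(theta))`` is
    minimized; standard errors come from the sandwich covariance with the
    full V, and the model chi-square is Browne's residual-based statistic
    (full-V weighted), so a saturated model scores chi2 = 0 exactly.
    ``model_spec`` maps factor name -> indicator list (default: the
    three-cluster NDV/COMP/MP structure).
    """
    if isinstance(gc_or_S, GeneticCovariance):
        S = gc_or_S.S
        V = gc_or_S.V
        traits = traits or gc_or_S.traits
    else:
        S = np.asarray(gc_or_S, dtype=float)
        if V is None:
            raise ValueError("V is required when S is passed as an array")
    k = S.shape[0]
    traits = traits or [f"t{i + 1}" for i in range(k)]
    spec = model_spec or {
        f: [t for t in ind if t in traits]
        for f, ind in DEFAULT_MODEL_SPEC.items()
    }
    model = _CFAModel(traits, spec)
    s_obs = vech(S)
    w = 1.0 / np.clip(np.diag(V), 1e-12, None)

    def resid(theta: np.ndarray) -> np.ndarray:
        return s_obs - vech(model.implied(theta))

    def objective(theta: np.ndarray) -> float:
        r = resid(theta)
        val = float(r @ (w * r))
        return val if np.isfinite(val) else 1e12

    res = optimize.minimize(
        objective,
        model.start(S),
        method="L-BFGS-B",
        bounds=model.bounds(),
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-12},
    )
    theta = res.x
    lam, phi, resid_var = model.unpack(theta)
    implied = model.implied(theta)
    jac = _numeric_jacobian(lambda t: vech(model.implied(t)), theta)
    # sandwich covariance of theta: (J'WJ)^-1 J'W V W J (J'WJ)^-1
    jw = jac.T * w
    bread = np.linalg.pinv(jw @ jac)
    cov = bread @ jw @ V @ jw.T @ bread.T
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    df = len(s_obs) - model.n_free
    chi2, cfi, srmr = _fit_indices(
        s_obs, V, resid(theta), jac, df, S, implied
    )
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    params = pd.DataFrame(
        {"param": model.param_names(), "estimate": theta, "se": se}
    )
    return CFAFit(
        params=params,
        chi2=chi2,
        df=df,
        p=p,
        aic=chi2 + 2 * model.n_free,
        cfi=cfi,
        srmr=srmr,
        implied=implied,
        loadings=lam,
        phi=phi,
        resid_var=resid_var,
        traits=traits,
        factors=model.factors,
    )


# ---------------------------------------------------------------------------
# Common-factor GWAS
# ---------------------------------------------------------------------------


def common_factor_gwas(
    gc: GeneticCovariance,
    sumstats: dict[str, pd.DataFrame],
    ref_freqs: pd.DataFrame | None = None,
    model_spec: dict[str, list[str]] | None = None,
    cfa: CFAFit | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-SNP factor association statistics for each latent factor.

    Per-trait betas are standardized with the reference allele frequency,
    ``beta_std = z / sqrt(n * 2 p (1 - p))``; each SNP's vector of
    standardized covariances with the indicators is projected onto the
    latent factors through the measurement model fixed at the base CFA
    solution (weighted least squares; weights are the inverse per-trait
    sampling variances).  SNPs absent from any indicator are reported
    missing.  Returns one summary-statistic table per factor.
    """
    cfa = cfa or cfa_wls(gc, model_spec=model_spec)
    traits = cfa.traits
    frames = {t: sumstats[t] for t in traits}
    ref = frames[traits[0]]

    shared = set(ref["SNP"])
    for t in traits[1:]:
        shared &= set(frames[t]["SNP"])
    all_snps = set().union(*(set(f["SNP"]) for f in frames.values()))
    n_missing = len(all_snps - shared)
    if n_missing:
        log.warning(
            "%d SNPs absent from at least one indicator; reported missing",
            n_missing,
        )
    base = ref[ref["SNP"].isin(shared)][
        ["SNP", "CHR", "POS", "A1", "A2"]
    ].sort_values(["CHR", "POS"])
    order = base["SNP"].to_numpy()
    m = len(order)

    if ref_freqs is not None:
        freqs = ref_freqs.set_index("SNP").loc[order, "FREQ"].to_numpy(float)
    elif "FREQ" in ref.columns:
        freqs = ref.set_index("SNP").loc[order, "FREQ"].to_numpy(float)
    else:
        raise ValueError("reference allele frequencies are required")
    het = np.clip(2 * freqs * (1 - freqs), 1e-6, None)

    k = len(traits)
    z = np.empty((m, k))
    n = np.empty(k)
    for d, t in enumerate(traits):
        sub = frames[t].set_index("SNP").loc[order]
        z[:, d] = (sub["BETA"] / sub["SE"]).to_numpy(float)
        n[d] = float(sub["N"].mean())

    # beta_std[j, d] = z / sqrt(n_d * het_j); weights w[j, d] = n_d * het_j.
    # The SNP is exogenous: implied cov(SNP, indicator) = Lambda cov(SNP, F),
    # so the design matrix is the loading matrix itself and g estimates the
    # SNP -> factor regression (cov on the standardized scale).
    a = cfa.loadings  # k x nf
    ana = a.T @ (n[:, None] * a)  # nf x nf
    ana_inv = np.linalg.pinv(ana)
    # g_j = het_j^{-1/2} * ana_inv @ a' @ (sqrt(n) * z_j)
    proj = ana_inv @ (a.T * np.sqrt(n))  # nf x k
    g = (proj @ z.T).T / np.sqrt(het)[:, None]  # m x nf
    se_g = np.sqrt(np.diag(ana_inv))[None, :] / np.sqrt(het)[:, None]
    zstat = g / se_g
    pvals = np.clip(2 * stats.norm.sf(np.abs(zstat)), 1e-300, 1.0)
    n_eff = 1.0 / (se_g**2 * het[:, None])

    out: dict[str, pd.DataFrame] = {}
    for f_i, factor in enumerate(cfa.factors):
        df = base.copy().reset_index(drop=True)
        df["BETA"] = g[:, f_i]
        df["SE"] = se_g[:, f_i]
        df["Z"] = zstat[:, f_i]
        df["P"] = pvals[:, f_i]
        df["N"] = np.round(n_eff[:, f_i]).astype(int)
        df["FREQ"] = freqs
        out[factor] = df
    return out
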