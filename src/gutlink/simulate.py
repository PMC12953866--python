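"""Synthetic locus-scale GWAS/QTL studies under explicit causal scenarios.

Genotypes are drawn from a Gaussian-copula haplotype model with AR(1)
latent correlation: haplotype ``h_j = 1[z_j < Phi^{-1}(maf_j)]`` where the
latent ``z`` follows an AR(1) process with parameter ``ld_rho``, and the
genotype is the sum of two independent haplotypes.  Thresholding attenuates
correlation, so the LD panel reported with each study is the *implied
genotype correlation* of the copula (computed by quadrature over the
bivariate normal orthant), not the latent rho — that panel is what LD
clumping, HEIDI and colocalization should be fed.

Each scenario draws an independent genotype sample per trait (two-sample
design): the exposure phenotype is rebuilt from the same causal SNPs in the
outcome cohort, so only genetic effects transmit across samples.  Marginal
per-SNP simple-regression beta/se/p are computed exactly for every trait.

Scenarios
---------
``null``       exposure has cis effects, no exposure->outcome effect.
``causal``     outcome = alpha * exposure (genetically transmitted).
``pleiotropy`` causal plus direct SNP->outcome effects at the instruments.
``shared2``    one causal variant with direct effects on both traits.
``linkage``    two distinct causal variants in moderate LD (r^2 in (0.05, 0.9)).
``distinct2``  two distinct, effectively unlinked causal variants (r^2 < 0.05).
``shared3``    causal chain x -> y -> z through the same causal SNPs,
               in three independent cohorts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy import stats

from .sumstats import LDMatrix, LocusTable, write_ld, write_sumstats

SCENARIOS = ("null", "causal", "pleiotropy", "linkage", "shared2",
             "distinct2", "shared3")

#: Non-palindromic allele pairs used for simulated SNPs.
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]

_SNP_SPACING_BP = 1_000  # 1 kb between adjacent simulated SNPs


class ScenarioError(ValueError):
    """Scenario specification is internally inconsistent."""


@dataclass
class ScenarioSpec:
    """Fully explicit description of one simulated locus study."""

    name: str
    m_snps: int
    maf: np.ndarray
    ld_rho: float
    causal_idx: dict[str, list[int]]
    causal_beta: dict[str, list[float]]
    alpha: tuple[float, ...]  # causal chain coefficients (x->y[, y->z])
    pleio_gamma: dict[int, float]
    n_exposure: int
    n_outcome: int
    n_third: int | None
    seed: int
    rint_outcome: bool = False

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS:
            raise ScenarioError(f"unknown scenario {self.name!r}")
        self.maf = np.asarray(self.maf, dtype=float)
        if len(self.maf) != self.m_snps:
            raise ScenarioError("maf length must equal m_snps")
        if np.any((self.maf <= 0) | (self.maf >= 1)):
            raise ScenarioError("maf must lie in (0, 1)")
        if not 0 <= self.ld_rho < 1:
            raise ScenarioError("ld_rho must lie in [0, 1)")
        for n in (self.n_exposure, self.n_outcome):
            if n <= 0:
                raise ScenarioError("sample sizes must be positive")
        for trait, idx in self.causal_idx.items():
            if any(i < 0 or i >= self.m_snps for i in idx):
                raise ScenarioError(f"causal index out of range for {trait}")
            if len(idx) != len(self.causal_beta.get(trait, [])):
                raise ScenarioError(f"causal_idx/causal_beta mismatch for {trait}")
        if self.name == "linkage":
            ei = self.causal_idx.get("exposure", [])
            oi = self.causal_idx.get("outcome", [])
            if not ei or not oi or set(ei) & set(oi):
                raise ScenarioError("linkage requires two distinct causal indices")
        if not isinstance(self.alpha, tuple):
            self.alpha = (float(self.alpha),)


@dataclass
class SimulatedStudy:
    """Per-trait locus tables, the implied LD panel, and the ground truth."""

    tables: dict[str, LocusTable]
    ld: LDMatrix
    truth: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for trait, table in self.tables.items():
            write_sumstats(table, out / f"{trait}.tsv")
        write_ld(self.ld, out / "ld.tsv")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def implied_genotype_corr(maf: np.ndarray, ld_rho: float,
                          n_nodes: int = 64) -> np.ndarray:
    """Genotype correlation matrix implied by the AR(1) Gaussian copula.

    For SNPs i, j with latent correlation rho^|i-j| and thresholds
    t = Phi^{-1}(maf), the haplotype indicators have
    P11 = P(Z_i < t_i, Z_j < t_j), evaluated here by Gauss-Legendre
    quadrature of  P11 = maf_i * \\int_0^1 Phi((t_j - rho q(u))/sqrt(1-rho^2)) du
    with q(u) = Phi^{-1}(u * maf_i).  Genotype correlation equals haplotype
    correlation (sum of two iid haplotypes).
    """
    maf = np.asarray(maf, dtype=float)
    m = len(maf)
    t = stats.norm.ppf(maf)
    corr = np.eye(m)
    if ld_rho == 0 or m == 1:
        return corr
    nodes, weights = leggauss(n_nodes)
    u = 0.5 * (nodes + 1.0)          # map to (0, 1)
    w = 0.5 * weights
    for d in range(1, m):
        rho = ld_rho ** d
        if rho < 1e-6:
            break
        i = np.arange(0, m - d)
        j = i + d
        # quadrature over the truncated latent normal of SNP i
        q = stats.norm.ppf(u[None, :] * maf[i, None])      # (pairs, nodes)
        inner = stats.norm.cdf((t[j, None] - rho * q) / np.sqrt(1 - rho ** 2))
        p11 = maf[i] * (inner @ w)
        cov = p11 - maf[i] * maf[j]
        denom = np.sqrt(maf[i] * (1 - maf[i]) * maf[j] * (1 - maf[j]))
        corr[i, j] = corr[j, i] = cov / denom
    return corr


def simulate_genotypes(n: int, maf: np.ndarray, ld_rho: float,
                       seed: int | np.random.Generator) -> np.ndarray:
    """Draw an n x m genotype matrix (0/1/2) from the copula model."""
    if n <= 0:
        raise ValueError("n must be positive")
    maf = np.asarray(maf, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = len(maf)
    thresh = stats.norm.ppf(maf).astype(np.float32)
    geno = np.zeros((n, m), dtype=np.int8)
    scale = np.float32(np.sqrt(1.0 - ld_rho ** 2))
    for _ in range(2):  # two independent haplotypes
        z = rng.standard_normal((n, m), dtype=np.float32)
        if ld_rho > 0:
            for j in range(1, m):
                z[:, j] = ld_rho * z[:, j - 1] + scale * z[:, j]
        geno += z < thresh
    return geno


def marginal_stats(G: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Exact per-SNP simple-regression beta, SE, p and allele frequency."""
    n, m = G.shape
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", Gc, Gc)
    sxy = Gc.T @ yc
    syy = float(yc @ yc)
    sxx = np.where(sxx == 0, np.nan, sxx)
    beta = sxy / sxx
    rss = np.maximum(syy - beta * sxy, 0.0)
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    tstat = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pval = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    return pd.DataFrame({
        "beta": beta, "se": se, "pval": pval,
        "eaf": G.mean(axis=0) / 2.0, "n": n,
    })


def rank_inverse_normal(y: np.ndarray, offset: float = 0.5) -> np.ndarray:
    """Blom-style rank inverse-normal transform."""
    ranks = stats.rankdata(y)
    return stats.norm.ppf((ranks - offset) / len(y))


def _phenotype(G: np.ndarray, idx: list[int], beta: list[float],
               rng: np.random.Generator) -> np.ndarray:
    y = rng.standard_normal(G.shape[0])
    if idx:
        y = y + G[:, idx] @ np.asarray(beta, dtype=float)
    return y


def simulate_locus_study(spec: ScenarioSpec) -> SimulatedStudy:
    """Simulate marginal summary statistics for every trait of a scenario.

    Each trait gets an independent genotype cohort.  The exposure phenotype
    is re-generated in downstream cohorts from the same causal SNPs with
    fresh noise, so only genetic effects are transmitted, matching the
    two-sample MR design.
    """
    rng = np.random.default_rng(spec.seed)
    maf = spec.maf
    a1 = spec.alpha[0]
    a2 = spec.alpha[1] if len(spec.alpha) > 1 else 0.0

    e_idx = spec.causal_idx.get("exposure", [])
    e_beta = spec.causal_beta.get("exposure", [])
    o_idx = spec.causal_idx.get("outcome", [])
    o_beta = spec.causal_beta.get("outcome", [])

    samples: dict[str, pd.DataFrame] = {}

    G_exp = simulate_genotypes(spec.n_exposure, maf, spec.ld_rho, rng)
    x_exp = _phenotype(G_exp, e_idx, e_beta, rng)
    samples["exposure"] = marginal_stats(G_exp, x_exp)

    G_out = simulate_genotypes(spec.n_outcome, maf, spec.ld_rho, rng)
    x_in_out = _phenotype(G_out, e_idx, e_beta, rng)
    y_out = a1 * x_in_out + _phenotype(G_out, o_idx, o_beta, rng)
    for j, g in spec.pleio_gamma.items():
        y_out = y_out + g * G_out[:, j]
    if spec.rint_outcome:
        y_out = rank_inverse_normal(y_out)
    samples["outcome"] = marginal_stats(G_out, y_out)

    if spec.n_third:
        G_3 = simulate_genotypes(spec.n_third, maf, spec.ld_rho, rng)
        x_3 = _phenotype(G_3, e_idx, e_beta, rng)
        y_3 = a1 * x_3 + _phenotype(G_3, o_idx, o_beta, rng)
        z_3 = a2 * y_3 + rng.standard_normal(spec.n_third)
        samples["third"] = marginal_stats(G_3, z_3)

    # shared locus annotation (SNP ids, positions, alleles)
    m = spec.m_snps
    snp_ids = [f"rs{i + 1}" for i in range(m)]
    pos = 1 + np.arange(m) * _SNP_SPACING_BP
    pair_pick = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    alleles = [_ALLELE_PAIRS[k] for k in pair_pick]

    tables = {}
    for trait, stats_df in samples.items():
        df = pd.DataFrame({
            "snp": snp_ids, "chr": "1", "pos": pos,
            "effect_allele": [a for a, _ in alleles],
            "other_allele": [b for _, b in alleles],
            "beta": stats_df["beta"], "se": stats_df["se"],
            "pval": stats_df["pval"], "eaf": stats_df["eaf"],
            "n": stats_df["n"],
        })
        tables[trait] = LocusTable(trait, df)

    ld = LDMatrix(snp_ids, implied_genotype_corr(maf, spec.ld_rho))
    truth = {
        "scenario": spec.name, "seed": spec.seed,
        "alpha": list(spec.alpha),
        "causal_idx": {k: list(v) for k, v in spec.causal_idx.items()},
        "causal_beta": {k: list(map(float, v)) for k, v in spec.causal_beta.items()},
        "pleio_gamma": {str(k): float(v) for k, v in spec.pleio_gamma.items()},
        "m_snps": spec.m_snps, "ld_rho": spec.ld_rho,
        "n": {"exposure": spec.n_exposure, "outcome": spec.n_outcome,
              "third": spec.n_third},
        "rint_outcome": spec.rint_outcome,
        "abundance_transform": "rank-inverse-normal stand-in" if spec.rint_outcome else None,
    }
    return SimulatedStudy(tables, ld, truth)


def _spread_indices(m: int, k: int, min_gap: int = 10) -> list[int]:
    """k indices spread evenly across [5, m-5) with at least min_gap spacing."""
    lo, hi = 5, max(m - 5, 6)
    if k == 1:
        return [m // 2]
    idx = np.linspace(lo, hi - 1, k).round().astype(int)
    if len(idx) > 1 and np.min(np.diff(idx)) < min_gap:
        raise ScenarioError(f"m_snps={m} too small for {k} causal SNPs "
                            f"with gap {min_gap}")
    return idx.tolist()


def make_scenario(name: str, overrides: dict | None = None,
                  seed: int = 0) -> ScenarioSpec:
    """Build a fully populated ScenarioSpec with documented defaults.

    Defaults: m_snps=200, maf ~ Uniform(0.05, 0.5), ld_rho=0.7, exposure
    cohort 368 (transverse-colon scale), outcome cohort 18340 (16S
    microbiome GWAS scale).  ``overrides`` may replace any spec field;
    m_snps/maf/ld_rho overrides are applied before causal placement so
    derived constraints (linkage r^2 band etc.) are honoured.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}")
    ov = dict(overrides or {})
    rng = np.random.default_rng(seed)

    m = int(ov.pop("m_snps", 200))
    ld_rho = float(ov.pop("ld_rho", 0.7))
    maf = ov.pop("maf", None)
    if maf is None:
        maf = rng.uniform(0.05, 0.5, size=m)
    maf = np.asarray(maf, dtype=float)
    n_iv = int(ov.pop("n_instruments", 10))
    iv_beta = float(ov.pop("instrument_beta", 0.25))
    min_gap = int(ov.pop("min_gap", 10))

    base = dict(
        name=name, m_snps=m, maf=maf, ld_rho=ld_rho,
        causal_idx={}, causal_beta={}, alpha=(0.0,), pleio_gamma={},
        n_exposure=368, n_outcome=18_340, n_third=None, seed=seed,
        rint_outcome=False,
    )

    explicit_causal = "causal_idx" in ov

    if name in ("null", "causal", "pleiotropy"):
        if not explicit_causal:
            idx = _spread_indices(m, n_iv, min_gap)
            base["causal_idx"] = {"exposure": idx}
            # heterogeneous cis effect sizes, as real eQTLs have; the wide
            # spread also keeps Egger's regression-dilution intercept bias
            # negligible relative to the true effect variation
            spread = rng.uniform(0.5, 1.5, size=len(idx))
            base["causal_beta"] = {"exposure": list(iv_beta * spread)}
        if name != "null":
            base["alpha"] = (0.3,)
        if name == "pleiotropy" and not explicit_causal:
            base["pleio_gamma"] = {i: 0.05 for i in idx}
    elif name == "shared2":
        c = m // 2
        base["causal_idx"] = {"exposure": [c], "outcome": [c]}
        base["causal_beta"] = {"exposure": [0.3], "outcome": [0.3]}
    elif name in ("linkage", "distinct2"):
        corr = implied_genotype_corr(maf, ld_rho)
        c = m // 2
        want = ((0.05, 0.9) if name == "linkage" else (0.0, 0.05))
        j = None
        for d in range(1, m - c):
            r2 = corr[c, c + d] ** 2
            if want[0] < r2 < want[1] if name == "linkage" else r2 < want[1]:
                j = c + d
                break
        if j is None:
            raise ScenarioError(f"no SNP pair with r^2 in {want} at ld_rho={ld_rho}")
        base["causal_idx"] = {"exposure": [c], "outcome": [j]}
        base["causal_beta"] = {"exposure": [0.3], "outcome": [0.3]}
    elif name == "shared3":
        # one dominant causal variant (single-causal-variant colocalization
        # regime) plus two minor ones so the chain still has multiple IVs
        idx = _spread_indices(m, 3, min_gap)
        order = np.argsort([abs(i - m // 2) for i in idx])
        base["causal_idx"] = {"exposure": [idx[i] for i in order]}
        base["causal_beta"] = {"exposure": [2 * iv_beta, 0.2, 0.2]}
        base["alpha"] = (0.4, 0.5)
        base["n_third"] = 5_000

    base.update(ov)
    return ScenarioSpec(**base)
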