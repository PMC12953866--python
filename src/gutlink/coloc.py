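"""Pairwise Bayesian colocalization under the single-causal-variant model.

Per-SNP evidence is the Wakefield approximate Bayes factor.  With
V = se^2, z = beta / se and prior effect variance W,

    log ABF = 0.5 * log(V / (V + W)) + z^2 W / (2 (V + W)).

Hypothesis evidences are accumulated in log space over the locus:

    H0 no association; H1/H2 one trait only; H3 both traits, distinct
    causal variants; H4 both traits, one shared causal variant,

with per-SNP priors p1, p2 (single-trait) and p12 (shared).  The posterior
PP4 quantifies colocalization; following common practice PP4 > 0.5 is
"colocalized" and PP4 > 0.9 is tier-1 evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .sumstats import LocusTable

DEFAULT_PRIOR_SD = 0.15          # quantitative traits
DEFAULT_PRIOR_SD_CC = 0.2        # case-control traits (log-odds scale)


@dataclass
class ColocResult:
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_snps: int
    priors: tuple[float, float, float]
    lead_snp: str
    snp_h4_posterior: pd.Series | None = None

    @property
    def colocalized(self) -> bool:
        return self.pp4 > 0.5

    @property
    def tier1(self) -> bool:
        return self.pp4 > 0.9

    def as_dict(self) -> dict:
        return {"pp0": self.pp0, "pp1": self.pp1, "pp2": self.pp2,
                "pp3": self.pp3, "pp4": self.pp4, "n_snps": self.n_snps,
                "lead_snp": self.lead_snp}


def log_abf(beta, se, prior_sd: float = DEFAULT_PRIOR_SD) -> np.ndarray:
    """Wakefield log approximate Bayes factor (vectorized)."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    v = se ** 2
    w = prior_sd ** 2
    z2 = (beta / se) ** 2
    return 0.5 * np.log(v / (v + w)) + z2 * w / (2.0 * (v + w))


def log_abf_from_n(z, n, maf, prior_sd: float = DEFAULT_PRIOR_SD) -> np.ndarray:
    """Sample-size/MAF fallback when SEs are unavailable:
    approximates V by 1 / (2 n maf (1 - maf))."""
    z = np.asarray(z, dtype=float)
    v = 1.0 / (2.0 * np.asarray(n, dtype=float)
               * np.asarray(maf, dtype=float) * (1.0 - np.asarray(maf)))
    se = np.sqrt(v)
    return log_abf(z * se, se, prior_sd)


def _log_h3(s1: float, s2: float, s12: float) -> float:
    """log( sum_{i != j} exp(l1_i + l2_j) ) from the marginal log-sums."""
    # sum_{i!=j} = (sum_i)(sum_j) - sum_{i==j}; always > 0 for m >= 2
    diff = s12 - (s1 + s2)
    if diff >= 0:  # single-SNP locus (or numerically degenerate)
        return -np.inf
    return s1 + s2 + np.log1p(-np.exp(diff))


def coloc_posteriors(trait1: LocusTable, trait2: LocusTable,
                     p1: float = 1e-4, p2: float = 1e-4, p12: float = 1e-5,
                     prior_sd1: float = DEFAULT_PRIOR_SD,
                     prior_sd2: float = DEFAULT_PRIOR_SD) -> ColocResult:
    """Enumerate PP0-PP4 over the SNPs shared by both tables.

    ABFs depend on beta only through z^2, so allele orientation does not
    affect the result.  PP1/PP2 swap under trait swap; PP0/PP3/PP4 are
    symmetric.
    """
    d1 = trait1.df.set_index("snp")
    d2 = trait2.df.set_index("snp")
    shared = [s for s in d1.index if s in d2.index]
    if not shared:
        raise ValueError("traits share no SNPs")

    l1 = log_abf(d1.loc[shared, "beta"], d1.loc[shared, "se"], prior_sd1)
    l2 = log_abf(d2.loc[shared, "beta"], d2.loc[shared, "se"], prior_sd2)

    s1 = float(logsumexp(l1))
    s2 = float(logsumexp(l2))
    s12 = float(logsumexp(l1 + l2))

    lh = np.array([
        0.0,
        np.log(p1) + s1,
        np.log(p2) + s2,
        np.log(p1) + np.log(p2) + _log_h3(s1, s2, s12),
        np.log(p12) + s12,
    ])
    post = np.exp(lh - logsumexp(lh))
    post /= post.sum()

    h4_track = pd.Series(np.exp((l1 + l2) - s12), index=shared)
    lead = h4_track.idxmax()
    return ColocResult(*map(float, post), n_snps=len(shared),
                       priors=(p1, p2, p12), lead_snp=str(lead),
                       snp_h4_posterior=h4_track)
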