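"""SMR association statistic and the HEIDI linkage filter.

SMR tests the exposure-outcome association at the top cis SNP:
``T_SMR = z_x^2 z_y^2 / (z_x^2 + z_y^2)`` against chi-square(1).  HEIDI
(heterogeneity in dependent instruments) asks whether the per-SNP SMR
effects ``b_i = beta_out,i / beta_exp,i`` at SNPs in LD with the top SNP
are consistent with a single shared causal variant: under that null every
``b_i`` estimates the same quantity, so the differences
``d_i = b_i - b_top`` are zero in expectation.  ``T_HEIDI = sum z_d,i^2``
with the z_d covariance propagated from LD correlations and per-SNP SEs by
the delta method; its tail is evaluated by Satterthwaite moment matching of
a scaled chi-square to the covariance spectrum.  Pairs with HEIDI
p < 0.01 are interpreted as linkage (two distinct variants) and filtered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sumstats import LDMatrix, LocusTable

logger = logging.getLogger(__name__)


@dataclass
class HeidiResult:
    t_smr: float
    p_smr: float
    n_heidi_snps: int
    t_heidi: float | None
    p_heidi: float | None
    pass_filter: bool
    top_snp: str | None = None


def smr_test(z_exposure_top: float, z_outcome_top: float) -> tuple[float, float]:
    """SMR chi-square statistic and p at the top SNP."""
    zx2, zy2 = z_exposure_top ** 2, z_outcome_top ** 2
    if zx2 + zy2 == 0:
        return 0.0, 1.0
    t = zx2 * zy2 / (zx2 + zy2)
    return float(t), float(stats.chi2.sf(t, df=1))


def satterthwaite_p(t: float, cov: np.ndarray) -> float:
    """Tail probability of a quadratic form sum z_i^2, z ~ N(0, cov),
    by moment matching to a scaled chi-square (g * chi2_h)."""
    mean = float(np.trace(cov))
    var = 2.0 * float(np.sum(cov * cov))
    if mean <= 0 or var <= 0:
        return 1.0
    g = var / (2.0 * mean)
    h = 2.0 * mean ** 2 / var
    return float(stats.chi2.sf(t / g, df=h))


def _smr_effect_covariance(bx, sex, by, sey, r):
    """Delta-method covariance of b_i = by_i / bx_i across SNPs.

    Exposure and outcome come from non-overlapping cohorts, so their
    marginal estimates are independent; within a trait,
    cov(beta_i, beta_j) = r_ij se_i se_j.
    """
    b = by / bx
    # gradient terms: db/dby = 1/bx ; db/dbx = -by/bx^2
    gy = 1.0 / bx
    gx = -by / bx ** 2
    cov_y = r * np.outer(sey, sey)
    cov_x = r * np.outer(sex, sex)
    cov = np.outer(gy, gy) * cov_y + np.outer(gx, gx) * cov_x
    return b, cov


def heidi_test(exposure: LocusTable, outcome: LocusTable, ld: LDMatrix,
               top_snp: str | None = None,
               r2_band: tuple[float, float] = (0.05, 0.9),
               max_snps: int = 20, min_snps: int = 3) -> HeidiResult:
    """HEIDI test at a locus, plus the SMR statistic at the top SNP.

    Up to ``max_snps`` SNPs (strongest exposure association first) with
    panel r^2 to the top SNP inside ``r2_band`` are used.  With fewer than
    ``min_snps`` eligible SNPs the test is not evaluable: p_heidi is
    missing and the pair passes the filter with a logged caveat.
    """
    e = exposure.df.set_index("snp")
    o = outcome.df.set_index("snp")
    shared = [s for s in e.index if s in o.index and s in ld]
    if not shared:
        raise ValueError("no shared SNPs between exposure, outcome and LD panel")

    ze = (e.loc[shared, "beta"] / e.loc[shared, "se"]).to_numpy()
    if top_snp is None:
        top_snp = shared[int(np.argmax(np.abs(ze)))]
    elif top_snp not in shared:
        raise ValueError(f"top SNP {top_snp!r} absent from tables or LD panel")

    z_top_e = float(e.loc[top_snp, "beta"] / e.loc[top_snp, "se"])
    z_top_o = float(o.loc[top_snp, "beta"] / o.loc[top_snp, "se"])
    t_smr, p_smr = smr_test(z_top_e, z_top_o)

    elig = []
    for s, z in zip(shared, np.abs(ze)):
        if s == top_snp:
            continue
        r2 = ld.r2_between(s, top_snp)
        if r2_band[0] < r2 < r2_band[1]:
            elig.append((z, s))
    elig.sort(key=lambda t: (-t[0], t[1]))
    snps = [s for _, s in elig[:max_snps]]

    if len(snps) < min_snps:
        logger.warning("HEIDI not evaluable (%d eligible SNP(s) < %d); "
                       "pair passes with caveat", len(snps), min_snps)
        return HeidiResult(t_smr, p_smr, len(snps), None, None, True, top_snp)

    order = snps + [top_snp]
    bx = e.loc[order, "beta"].to_numpy()
    sex = e.loc[order, "se"].to_numpy()
    by = o.loc[order, "beta"].to_numpy()
    sey = o.loc[order, "se"].to_numpy()
    r = ld.submatrix(order).r
    b, cov_b = _smr_effect_covariance(bx, sex, by, sey, r)

    k = len(snps)
    # d_i = b_i - b_top ; J maps b (k+1) -> d (k)
    J = np.hstack([np.eye(k), -np.ones((k, 1))])
    d = J @ b
    cov_d = J @ cov_b @ J.T
    sd = np.sqrt(np.diag(cov_d))
    z_d = d / sd
    corr_d = cov_d / np.outer(sd, sd)
    t_heidi = float(np.sum(z_d ** 2))
    p_heidi = satterthwaite_p(t_heidi, corr_d)
    return HeidiResult(t_smr, p_smr, k, t_heidi, p_heidi,
                       p_heidi >= 0.01, top_snp)
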