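"""Two-sample Mendelian randomization estimators and QC.

The primary estimator is inverse-variance-weighted (IVW) meta-analysis of
per-instrument Wald ratios ``beta_out / beta_exp`` with first-order
(delta-method) SEs ``se_out / |beta_exp|``.  The default mode applies a
multiplicative random-effects scaling ``max(1, sqrt(Q / (J - 1)))`` to the
fixed-effect SE, where Q is Cochran's heterogeneity statistic.  QC follows
standard two-sample practice: pairs with a single instrument are refused,
MR-Egger's intercept screens for directional pleiotropy (pair excluded at
intercept p < 0.05), leave-one-out flags single-SNP-driven estimates, and
nominal p-values are adjusted by study-wise Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .sumstats import HarmonizedInstrumentTable

logger = logging.getLogger(__name__)


class SingleInstrumentError(ValueError):
    """Pair refused: estimates from a single IV are excluded."""

    reason_code = "single_iv"


@dataclass
class EggerResult:
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    intercept_p: float

    @property
    def passes(self) -> bool:
        return self.intercept_p >= 0.05


@dataclass
class MRResult:
    exposure_id: str
    outcome_id: str
    n_iv: int
    beta_ivw: float
    se_ivw: float
    p_ivw: float
    q_stat: float
    mode: str
    egger: EggerResult | None = None
    loo: pd.DataFrame | None = None
    loo_flagged: bool | None = None
    fdr_q: float | None = None
    pass_flags: dict = field(default_factory=dict)


def _wald_ratios(h: HarmonizedInstrumentTable) -> pd.DataFrame:
    df = h.df
    nonzero = df["beta_exp"] != 0
    if (~nonzero).any():
        logger.warning("%s->%s: dropped %d IV(s) with zero exposure beta",
                       h.exposure_id, h.outcome_id, int((~nonzero).sum()))
    df = df[nonzero]
    ratio = df["beta_out"] / df["beta_exp"]
    se = df["se_out"] / df["beta_exp"].abs()
    return pd.DataFrame({"snp": df["snp"], "ratio": ratio, "se": se,
                         "beta_exp": df["beta_exp"], "beta_out": df["beta_out"],
                         "se_out": df["se_out"]}).reset_index(drop=True)


def _ivw_core(ratio: np.ndarray, se: np.ndarray, mode: str):
    w = se ** -2.0
    beta = float(np.sum(w * ratio) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (ratio - beta) ** 2))
    j = len(ratio)
    if mode == "multiplicative_re":
        scale = max(1.0, np.sqrt(q / (j - 1))) if j > 1 else 1.0
        se_out = se_fixed * scale
    elif mode == "fixed":
        se_out = se_fixed
    else:
        raise ValueError(f"unknown IVW mode {mode!r}")
    p = float(2.0 * stats.norm.sf(abs(beta) / se_out))
    return beta, se_out, max(p, np.finfo(float).tiny), q


def mr_ivw(h: HarmonizedInstrumentTable,
           mode: str = "multiplicative_re") -> MRResult:
    """IVW causal estimate over the instruments of a harmonized table.

    Raises :class:`SingleInstrumentError` when fewer than two usable IVs
    remain (single-IV pairs are excluded from analysis).
    """
    ratios = _wald_ratios(h)
    if len(ratios) < 2:
        raise SingleInstrumentError(
            f"{h.exposure_id}->{h.outcome_id}: {len(ratios)} usable IV(s); "
            "pairs inferred from single IVs are excluded")
    beta, se, p, q = _ivw_core(ratios["ratio"].to_numpy(),
                               ratios["se"].to_numpy(), mode)
    return MRResult(h.exposure_id, h.outcome_id, len(ratios),
                    beta, se, p, q, mode)


def mr_egger(h: HarmonizedInstrumentTable) -> EggerResult | None:
    """MR-Egger regression; ``None`` (screen passes by default) when n_iv < 3.

    Instruments are oriented so every exposure beta is positive, then
    ``beta_out`` is regressed on ``beta_exp`` with weights ``se_out^-2``
    and a free intercept; the intercept's t-test (J - 2 df) screens for
    directional pleiotropy.
    """
    ratios = _wald_ratios(h)
    if len(ratios) < 3:
        logger.warning("%s->%s: %d IV(s) < 3, Egger screen skipped "
                       "(passes by default)", h.exposure_id, h.outcome_id,
                       len(ratios))
        return None
    sign = np.sign(ratios["beta_exp"].to_numpy())
    bx = ratios["beta_exp"].to_numpy() * sign
    by = ratios["beta_out"].to_numpy() * sign
    w = ratios["se_out"].to_numpy() ** -2.0
    fit = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
    return EggerResult(
        slope=float(fit.params[1]), slope_se=float(fit.bse[1]),
        intercept=float(fit.params[0]), intercept_se=float(fit.bse[0]),
        intercept_p=float(fit.pvalues[0]),
    )


def leave_one_out(h: HarmonizedInstrumentTable,
                  mode: str = "multiplicative_re",
                  alpha: float = 0.05) -> tuple[pd.DataFrame | None, bool | None]:
    """Recompute IVW dropping each IV in turn.

    Returns ``(per-IV re-estimates, flagged)``; flagged is True when any
    single drop flips the estimate's sign or moves its Wald p across
    ``alpha``.  Not applicable (``(None, None)``) below 3 IVs.
    """
    ratios = _wald_ratios(h)
    j = len(ratios)
    if j < 3:
        return None, None
    full_beta, _, full_p, _ = _ivw_core(ratios["ratio"].to_numpy(),
                                        ratios["se"].to_numpy(), mode)
    rows = []
    flagged = False
    r = ratios["ratio"].to_numpy()
    s = ratios["se"].to_numpy()
    for i in range(j):
        keep = np.arange(j) != i
        b, se, p, q = _ivw_core(r[keep], s[keep], mode)
        flip = (np.sign(b) != np.sign(full_beta)) or \
               ((p < alpha) != (full_p < alpha))
        flagged = flagged or flip
        rows.append({"dropped_snp": ratios["snp"].iloc[i], "beta": b,
                     "se": se, "p": p, "delta_beta": b - full_beta,
                     "influential": flip})
    return pd.DataFrame(rows), flagged


def bh_fdr(pvals, scope_labels=None) -> np.ndarray:
    """Benjamini-Hochberg q-values, computed within each scope group."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    q = np.empty_like(p)
    if scope_labels is None:
        scope_labels = np.zeros(len(p))
    labels = pd.Series(scope_labels)
    for _, idx in labels.groupby(labels).groups.items():
        idx = np.asarray(idx)
        q[idx] = multipletests(p[idx], method="fdr_bh")[1]
    return q


def two_step_mr(step1: pd.DataFrame, step2: pd.DataFrame,
                step1_rule=None, step2_rule=None) -> pd.DataFrame:
    """Chain gene->genus and genus->trait MR results into supported triads.

    ``step1`` rows need columns gene, genus, beta, se plus the boolean QC
    flags consulted by ``step1_rule`` (default: fdr_ok & egger_ok &
    heidi_ok); ``step2`` rows need genus, trait, beta, se, pval
    (``step2_rule`` default: nominal p < 0.05).  The chained effect is
    ``beta1 * beta2`` with first-order SE
    ``sqrt(beta2^2 se1^2 + beta1^2 se2^2)``.
    """
    if step1_rule is None:
        step1_rule = lambda r: bool(r.get("fdr_ok", False)
                                    and r.get("egger_ok", True)
                                    and r.get("heidi_ok", True))
    if step2_rule is None:
        step2_rule = lambda r: r["pval"] < 0.05

    s1 = step1[[step1_rule(row) for _, row in step1.iterrows()]]
    s2 = step2[[step2_rule(row) for _, row in step2.iterrows()]]
    merged = s1.merge(s2, on="genus", suffixes=("_1", "_2"))
    if merged.empty:
        return pd.DataFrame(columns=["gene", "genus", "trait", "beta_chain",
                                     "se_chain"])
    b1, b2 = merged["beta_1"], merged["beta_2"]
    s1e, s2e = merged["se_1"], merged["se_2"]
    merged["beta_chain"] = b1 * b2
    merged["se_chain"] = np.sqrt(b2 ** 2 * s1e ** 2 + b1 ** 2 * s2e ** 2)
    return merged[["gene", "genus", "trait", "beta_chain", "se_chain"]
                  + [c for c in merged.columns
                     if c not in ("gene", "genus", "trait", "beta_chain", "se_chain")]]
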