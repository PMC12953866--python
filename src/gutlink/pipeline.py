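"""End-to-end orchestration of the MR + colocalization cascade.

A forward run takes, for every (gene, tissue, genus) unit, the exposure and
outcome locus tables plus an LD panel, and executes:

    select_ivs -> ld_clump -> harmonize -> mr_ivw -> mr_egger ->
    leave_one_out -> heidi -> study-wise BH FDR -> coloc

emitting one row per unit with the causal estimate, every QC statistic and
the filter verdicts.  The filter cascade is: multi-IV requirement, Egger
intercept screen (p < 0.05 excluded), HEIDI screen (p < 0.01 excluded),
study-wise FDR (q < 0.05 required); each filtered unit is logged with a
reason code.  The reverse (microbiome -> gene / methylation) direction uses
the same machinery with swapped roles and the mbQTL instrument threshold;
disease integration runs three-trait colocalization on
(eQTL, mbQTL, GWAS) triads and cross-references two-step MR support.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import __version__
from .coloc import coloc_posteriors
from .instruments import ld_clump, select_ivs
from .moloc import moloc_posteriors
from .mr import (SingleInstrumentError, bh_fdr, leave_one_out, mr_egger,
                 mr_ivw, two_step_mr)
from .smr import heidi_test
from .sumstats import LDMatrix, LocusTable, harmonize_pair

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds and knobs of one pipeline run (defaults are the study's)."""

    direction: str = "forward"          # forward | reverse | disease
    iv_p_eqtl: float = 5e-8
    iv_p_mbqtl: float = 1e-5
    clump_r2: float = 0.01
    clump_kb: float = 100.0
    fdr: float = 0.05
    egger_alpha: float = 0.05
    heidi_alpha: float = 0.01
    pp4_min: float = 0.5
    ppabc_min: float = 0.1
    palindrome_band: float = 0.08
    ivw_mode: str = "multiplicative_re"
    fdr_scope: str = "global"           # global | per_tissue
    require_coloc_for_disease: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("iv_p_eqtl", "iv_p_mbqtl", "clump_r2", "fdr",
                     "egger_alpha", "heidi_alpha", "pp4_min", "ppabc_min"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.clump_kb <= 0:
            raise ValueError("clump_kb must be positive")
        if self.direction not in ("forward", "reverse", "disease"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def iv_pthresh(self) -> float:
        return self.iv_p_mbqtl if self.direction == "reverse" else self.iv_p_eqtl

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        """Load a flat key-value YAML config; keyword overrides win."""
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a flat mapping")
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PairInput:
    """One analysis unit: a gene locus against one genus (or any
    exposure/outcome role assignment)."""

    gene: str
    tissue: str
    genus: str
    exposure: LocusTable
    outcome: LocusTable
    ld: LDMatrix


def run_pair(unit: PairInput, config: RunConfig) -> dict:
    """Run the per-unit cascade (everything except FDR, which is
    study-wise).  Returns a flat result row; failures record a reason."""
    row = {"gene": unit.gene, "tissue": unit.tissue, "genus": unit.genus,
           "filter_reason": ""}
    candidates = select_ivs(unit.exposure, config.iv_pthresh)
    if not candidates:
        row["filter_reason"] = "no_instruments"
        return row
    iv_set = ld_clump(unit.exposure.subset(candidates), unit.ld,
                      r2_max=config.clump_r2, window_kb=config.clump_kb)
    harmonized = harmonize_pair(unit.exposure, unit.outcome,
                                palindrome_band=config.palindrome_band)
    h_iv = harmonized.subset(iv_set.snp_ids)
    row["n_iv"] = len(h_iv)
    try:
        res = mr_ivw(h_iv, mode=config.ivw_mode)
    except SingleInstrumentError:
        row["filter_reason"] = "single_iv"
        logger.info("%s/%s->%s filtered: single_iv", unit.gene, unit.tissue,
                    unit.genus)
        return row
    row.update(beta=res.beta_ivw, se=res.se_ivw, pval=res.p_ivw,
               q_stat=res.q_stat, n_iv=res.n_iv)

    egger = mr_egger(h_iv)
    if egger is not None:
        row.update(egger_intercept=egger.intercept,
                   egger_intercept_p=egger.intercept_p)
        row["egger_ok"] = egger.intercept_p >= config.egger_alpha
    else:
        row["egger_ok"] = True  # screen not evaluable; passes with caveat
    loo, loo_flagged = leave_one_out(h_iv, mode=config.ivw_mode)
    row["loo_flagged"] = loo_flagged

    heidi = heidi_test(unit.exposure, unit.outcome, unit.ld)
    row.update(t_smr=heidi.t_smr, p_smr=heidi.p_smr,
               p_heidi=heidi.p_heidi, heidi_snps=heidi.n_heidi_snps)
    row["heidi_ok"] = (heidi.p_heidi is None
                       or heidi.p_heidi >= config.heidi_alpha)

    cres = coloc_posteriors(unit.exposure, unit.outcome)
    row.update(pp0=cres.pp0, pp1=cres.pp1, pp2=cres.pp2, pp3=cres.pp3,
               pp4=cres.pp4, coloc_lead=cres.lead_snp)
    row["colocalized"] = cres.pp4 > config.pp4_min
    row["coloc_tier1"] = cres.pp4 > 0.9

    if not row["egger_ok"]:
        row["filter_reason"] = "egger"
    elif not row["heidi_ok"]:
        row["filter_reason"] = "heidi"
    if row["filter_reason"]:
        logger.info("%s/%s->%s filtered: %s", unit.gene, unit.tissue,
                    unit.genus, row["filter_reason"])
    return row


def run_forward(units: Iterable[PairInput], config: RunConfig | None = None,
                out_dir=None) -> pd.DataFrame:
    """Run the cascade over all units and apply study-wise FDR.

    ``significant`` requires multi-IV, Egger pass, HEIDI pass and FDR
    q < threshold.  With ``out_dir`` set, writes the result TSV and a JSON
    manifest keyed by the config hash.
    """
    config = config or RunConfig()
    rows = [run_pair(u, config) for u in units]
    df = pd.DataFrame(rows)
    if df.empty:
        return df

    tested = df["pval"].notna() if "pval" in df else pd.Series(False, index=df.index)
    df["fdr_q"] = np.nan
    if tested.any():
        scopes = (df.loc[tested, "tissue"] if config.fdr_scope == "per_tissue"
                  else None)
        df.loc[tested, "fdr_q"] = bh_fdr(df.loc[tested, "pval"].to_numpy(),
                                         scopes)
    df["fdr_ok"] = df["fdr_q"] < config.fdr
    mask = tested & ~df["fdr_ok"] & (df["filter_reason"] == "")
    df.loc[mask, "filter_reason"] = "fdr"
    egger_ok = (df["egger_ok"].fillna(False).astype(bool)
                if "egger_ok" in df else True)
    heidi_ok = (df["heidi_ok"].fillna(False).astype(bool)
                if "heidi_ok" in df else True)
    df["significant"] = tested & df["fdr_ok"] & egger_ok & heidi_ok
    df["config_hash"] = config.config_hash()

    if out_dir is not None:
        _write_outputs(df, config, out_dir, stage="forward")
    return df


@dataclass
class TriadInput:
    """(gene eQTL, genus mbQTL, disease GWAS) tables at one locus."""

    gene: str
    genus: str
    trait: str
    eqtl: LocusTable
    mbqtl: LocusTable
    gwas: LocusTable
    ld: LDMatrix
    tissue: str = ""


def run_disease(triads: Iterable[TriadInput],
                config: RunConfig | None = None,
                out_dir=None) -> pd.DataFrame:
    """Disease integration: per triad, three-trait colocalization plus
    two-step MR (gene -> genus with eQTL instruments, genus -> trait with
    mbQTL instruments)."""
    config = config or RunConfig(direction="disease")
    rows = []
    step1_rows, step2_rows = [], []
    for tri in triads:
        row = {"gene": tri.gene, "genus": tri.genus, "trait": tri.trait,
               "tissue": tri.tissue}
        mres = moloc_posteriors({"a": tri.eqtl, "b": tri.mbqtl, "c": tri.gwas})
        row["pp_abc"] = mres.pp_abc
        row["moloc_modal"] = mres.modal_configuration
        row["moloc_colocalized"] = mres.pp_abc > config.ppabc_min

        cfg1 = dataclasses.replace(config, direction="forward")
        r1 = run_pair(PairInput(tri.gene, tri.tissue, tri.genus,
                                tri.eqtl, tri.mbqtl, tri.ld), cfg1)
        cfg2 = dataclasses.replace(config, direction="reverse")
        r2 = run_pair(PairInput(tri.genus, tri.tissue, tri.trait,
                                tri.mbqtl, tri.gwas, tri.ld), cfg2)
        if r1.get("pval") is not None and not np.isnan(r1.get("pval", np.nan)):
            step1_rows.append({"gene": tri.gene, "genus": tri.genus,
                               "beta": r1["beta"], "se": r1["se"],
                               "pval": r1["pval"],
                               "egger_ok": r1.get("egger_ok", True),
                               "heidi_ok": r1.get("heidi_ok", True)})
        if r2.get("pval") is not None and not np.isnan(r2.get("pval", np.nan)):
            step2_rows.append({"genus": tri.genus, "trait": tri.trait,
                               "beta": r2["beta"], "se": r2["se"],
                               "pval": r2["pval"]})
        row["step1_pval"] = r1.get("pval", np.nan)
        row["step2_pval"] = r2.get("pval", np.nan)
        rows.append(row)

    df = pd.DataFrame(rows)
    if df.empty:
        return df

    s1 = pd.DataFrame(step1_rows)
    if len(s1):
        s1["fdr_q"] = bh_fdr(s1["pval"].to_numpy())
        s1["fdr_ok"] = s1["fdr_q"] < config.fdr
    s2 = pd.DataFrame(step2_rows)
    triads_df = two_step_mr(s1, s2) if len(s1) and len(s2) else pd.DataFrame(
        columns=["gene", "genus", "trait"])
    supported = set(map(tuple, triads_df[["gene", "genus", "trait"]].to_numpy()))
    df["two_step_supported"] = [
        (g, m, t) in supported
        for g, m, t in df[["gene", "genus", "trait"]].to_numpy()]
    df["triad_flagged"] = df["moloc_colocalized"] & df["two_step_supported"]
    df["config_hash"] = config.config_hash()
    if out_dir is not None:
        _write_outputs(df, config, out_dir, stage="disease")
    return df


def _write_outputs(df: pd.DataFrame, config: RunConfig, out_dir,
                   stage: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / f"{stage}_results.tsv", sep="\t", index=False)
    manifest = {
        "stage": stage,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_rows": int(len(df)),
        "package_version": __version__,
    }
    # manifests are content-addressed: a changed config never overwrites
    path = out / f"manifest_{stage}_{config.config_hash()}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
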