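import numpy as np
import pandas as pd
import pytest

from gutlink import LocusTable


def build_table(trait="trait", snps=None, beta=None, se=None, pval=None,
                eaf=None, pos=None, effect_allele=None, other_allele=None,
                n=1000, chrom="1"):
    """Construct a LocusTable from plain vectors with sensible fill-ins."""
    m = len(snps)
    beta = np.asarray(beta, float)
    se = np.full(m, 0.05) if se is None else np.asarray(se, float)
    if pval is None:
        from scipy import stats
        pval = 2 * stats.norm.sf(np.abs(beta / se))
        pval = np.clip(pval, 1e-300, 1.0)
    df = pd.DataFrame({
        "snp": snps,
        "chr": chrom,
        "pos": pos if pos is not None else 1 + np.arange(m) * 1000,
        "effect_allele": effect_allele if effect_allele is not None else ["A"] * m,
        "other_allele": other_allele if other_allele is not None else ["G"] * m,
        "beta": beta,
        "se": se,
        "pval": pval,
        "eaf": eaf if eaf is not None else [0.3] * m,
        "n": n,
    })
    return LocusTable(trait, df)


def build_harmonized(bx, by, sex=None, sey=None, exposure="e", outcome="o"):
    """Construct a HarmonizedInstrumentTable straight from effect vectors."""
    from gutlink import HarmonizedInstrumentTable
    m = len(bx)
    bx, by = np.asarray(bx, float), np.asarray(by, float)
    sex = np.full(m, 0.02) if sex is None else np.asarray(sex, float)
    sey = np.full(m, 0.02) if sey is None else np.asarray(sey, float)
    df = pd.DataFrame({
        "snp": [f"rs{i+1}" for i in range(m)],
        "chr": "1", "pos": 1 + np.arange(m) * 1000,
        "effect_allele": "A", "other_allele": "G",
        "beta_exp": bx, "se_exp": sex, "pval_exp": 1e-9, "eaf_exp": 0.3,
        "n_exp": 10_000,
        "beta_out": by, "se_out": sey, "pval_out": 0.5, "eaf_out": 0.3,
        "n_out": 10_000,
    })
    return HarmonizedInstrumentTable(exposure, outcome, df)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_ld(m, seed, n=200):
    """A valid random LD matrix (empirical correlation of Gaussian data)."""
    from gutlink import LDMatrix
    g = np.random.default_rng(seed).standard_normal((n, m))
    r = np.corrcoef(g, rowvar=False)
    return LDMatrix([f"rs{i+1}" for i in range(m)], r)
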