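"""Multi-trait (three-way) Bayesian colocalization.

Each configuration states, for every trait, whether it is associated at the
locus and which associated traits share a causal variant: formally, the
all-null configuration plus, for every non-empty subset of traits, every
partition of that subset into shared-causal-variant groups.  For three
traits a, b, c this gives 1 + 3 + 6 + 5 = 15 configurations, labelled e.g.
``"ab.c"`` (a and b share one variant, c has its own distinct variant),
``"abc"`` (all three share), ``"a.b"`` (both associated, distinct
variants), ``"null"``.

Evidence for a configuration sums, over assignments of *distinct* SNPs to
its groups, the product over groups of the joint Wakefield ABFs of the
group's traits, weighted by a per-SNP prior that depends on group size
(p1/p2/p3 for 1/2/3 traits sharing).  The distinct-assignment sums are
evaluated by inclusion-exclusion over coincidence patterns, in log space.
``PP_abc`` — the posterior of the single all-shared configuration — is the
colocalization evidence; a threshold of 0.1 flags a locus as colocalized
across all three traits.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .coloc import DEFAULT_PRIOR_SD, log_abf
from .sumstats import LocusTable

DEFAULT_PRIORS = (1e-4, 1e-6, 1e-7)  # per-SNP prior for group sizes 1, 2, 3

_TRAIT_LETTERS = "abcd"


class _Partitions:
    """Set partitions of a tuple, smallest-first deterministic order."""

    @staticmethod
    def of(items: tuple):
        items = list(items)
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in _Partitions.of(tuple(rest)):
            # put `first` in its own group, or join each existing group
            yield [[first]] + part
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1:]


def enumerate_configurations(n_traits: int) -> list[str]:
    """All association configurations for ``n_traits`` traits (1-4).

    A label joins shared-variant groups with ``.``; the empty
    configuration is ``"null"``.  Count = 1 + sum over non-empty subsets S
    of Bell-partitions of S (15 for three traits, 5 for two).
    """
    if not 1 <= n_traits <= 4:
        raise ValueError("n_traits must be between 1 and 4")
    letters = _TRAIT_LETTERS[:n_traits]
    labels = ["null"]
    for k in range(1, n_traits + 1):
        for subset in combinations(letters, k):
            for part in _Partitions.of(subset):
                groups = sorted("".join(sorted(g)) for g in part)
                labels.append(".".join(groups))
    # deterministic, duplicate-free ordering
    seen = []
    for lab in labels:
        if lab not in seen:
            seen.append(lab)
    return seen


def _log_distinct_sum(group_logs: list[np.ndarray]) -> float:
    """log sum over assignments of distinct SNPs to groups of
    prod_g exp(group_logs[g][snp_g]), by inclusion-exclusion (k <= 3)."""
    k = len(group_logs)
    if k == 1:
        return float(logsumexp(group_logs[0]))
    if k == 2:
        a, b = group_logs
        s_ab = logsumexp(a) + logsumexp(b)
        s_eq = logsumexp(a + b)
        terms = np.array([s_ab, s_eq])
        signs = np.array([1.0, -1.0])
    elif k == 3:
        a, b, c = group_logs
        sa, sb, sc = logsumexp(a), logsumexp(b), logsumexp(c)
        terms = np.array([
            sa + sb + sc,
            logsumexp(a + b) + sc,
            logsumexp(a + c) + sb,
            logsumexp(b + c) + sa,
            logsumexp(a + b + c) + np.log(2.0),
        ])
        signs = np.array([1.0, -1.0, -1.0, -1.0, 1.0])
    else:
        raise ValueError("at most 3 groups supported")
    mx = float(np.max(terms))
    total = float(np.sum(signs * np.exp(terms - mx)))
    if total <= 0:  # fewer SNPs than groups, or cancellation to zero
        return -np.inf
    return mx + np.log(total)


@dataclass
class MolocResult:
    config_posteriors: dict[str, float]
    pp_abc: float
    priors: tuple[float, float, float]
    lead_snp: str
    n_snps: int

    @property
    def colocalized(self) -> bool:
        return self.pp_abc > 0.1

    @property
    def modal_configuration(self) -> str:
        return max(self.config_posteriors, key=self.config_posteriors.get)


def moloc_posteriors(tables: dict[str, LocusTable] | list[LocusTable],
                     priors: tuple[float, float, float] = DEFAULT_PRIORS,
                     prior_sd: float = DEFAULT_PRIOR_SD) -> MolocResult:
    """Posterior over association configurations for 2-3 traits.

    ``tables`` maps trait letters (``a``, ``b``, ``c`` in order) to locus
    tables; a list is labelled in order.  Returns posteriors over the full
    configuration set, with ``pp_abc`` the all-shared posterior (for three
    traits).
    """
    if isinstance(tables, dict):
        tabs = list(tables.values())
    else:
        tabs = list(tables)
    n_traits = len(tabs)
    if not 2 <= n_traits <= 3:
        raise ValueError("moloc supports 2 or 3 traits")
    letters = _TRAIT_LETTERS[:n_traits]

    dfs = [t.df.set_index("snp") for t in tabs]
    shared = [s for s in dfs[0].index if all(s in d.index for d in dfs[1:])]
    if not shared:
        raise ValueError("traits share no SNPs")
    labf = {
        letter: log_abf(d.loc[shared, "beta"], d.loc[shared, "se"], prior_sd)
        for letter, d in zip(letters, dfs)
    }

    labels = enumerate_configurations(n_traits)
    log_ev = {}
    for lab in labels:
        if lab == "null":
            log_ev[lab] = 0.0
            continue
        groups = lab.split(".")
        group_logs = []
        lprior = 0.0
        for g in groups:
            vec = np.sum([labf[t] for t in g], axis=0)
            lprior += np.log(priors[len(g) - 1])
            group_logs.append(np.asarray(vec, dtype=float))
        log_ev[lab] = lprior + _log_distinct_sum(group_logs)

    vals = np.array([log_ev[lab] for lab in labels])
    post = np.exp(vals - logsumexp(vals))
    post /= post.sum()
    config_post = {lab: float(p) for lab, p in zip(labels, post)}

    all_shared = "".join(letters)
    joint = np.sum([labf[t] for t in letters], axis=0)
    lead = shared[int(np.argmax(joint))]
    return MolocResult(config_post, config_post[all_shared],
                       tuple(priors), str(lead), len(shared))


def locus_compare_table(tables: dict[str, LocusTable],
                        ld=None, lead_snp: str | None = None) -> pd.DataFrame:
    """Per-SNP -log10 p for each trait plus LD (r^2) to a lead SNP, the
    plotting companion for locus-compare-style figures."""
    dfs = {k: t.df.set_index("snp") for k, t in tables.items()}
    shared = None
    for d in dfs.values():
        shared = d.index if shared is None else shared.intersection(d.index)
    out = pd.DataFrame(index=shared)
    first = next(iter(dfs.values()))
    out["pos"] = first.loc[shared, "pos"]
    for k, d in dfs.items():
        out[f"neglog10p_{k}"] = -np.log10(d.loc[shared, "pval"])
    if ld is not None and lead_snp is not None:
        out["r2_lead"] = [ld.r2_between(s, lead_snp) if s in ld else np.nan
                          for s in shared]
    return out.reset_index(names="snp")
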