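"""Gene-set statistics: resampling overlap enrichment between two gene
sets, hypergeometric term over-representation, and the per-impact
variant-density comparison between ASEGs and the genomic background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")


@dataclass
class OverlapTestResult:
    observed_overlap: int
    null_mean: float
    null_sd: float
    n_sim: int
    t_stat: float
    p_t: float
    p_empirical: float


def overlap_resampling_test(set_a: Iterable[str], set_b: Iterable[str],
                            universe: Sequence[str], n_sim: int = 1000,
                            seed: int | None = None,
                            rng: np.random.Generator | None = None) -> OverlapTestResult:
    """Is the overlap of two gene sets larger than random sampling expects?

    Each of ``n_sim`` simulations draws |A| and |B| genes uniformly
    without replacement from the universe and records the intersection
    size.  Two p-values are reported: a one-sample t-test of the null
    draws against the observed overlap (t signed so that positive means
    observed above the null mean), and the recommended empirical
    p = (1 + #{null >= observed}) / (n_sim + 1).
    """
    set_a, set_b = set(set_a), set(set_b)
    universe = list(universe)
    uni = set(universe)
    if not set_a <= uni or not set_b <= uni:
        raise ValueError("both sets must be subsets of the universe")
    if n_sim < 2:
        raise ValueError("n_sim must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = len(set_a & set_b)
    n, ka, kb = len(universe), len(set_a), len(set_b)
    null = np.empty(n_sim, dtype=np.int64)
    for i in range(n_sim):
        a = rng.choice(n, size=ka, replace=False)
        b = rng.choice(n, size=kb, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[a] = True
        null[i] = mask[b].sum()
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    if null_sd > 0:
        t_res = stats.ttest_1samp(null, popmean=observed)
        t_stat = -float(t_res.statistic)  # positive = observed above null mean
        p_t = float(t_res.pvalue)
    else:
        t_stat = np.inf if observed != null_mean else 0.0
        p_t = 0.0 if observed != null_mean else 1.0
    p_emp = (1 + int((null >= observed).sum())) / (n_sim + 1)
    return OverlapTestResult(observed, null_mean, null_sd, n_sim, t_stat, p_t, p_emp)


def hypergeom_enrichment(query: Iterable[str],
                         term_map: pd.DataFrame | Mapping[str, Iterable[str]],
                         universe: Iterable[str]) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each term.

    For a term annotating K of the N universe genes, of which k fall in
    the n-gene query, p = P[X >= k], X ~ Hypergeom(N, K, n); BH across
    terms; sorted by p.  Term memberships outside the universe are
    ignored.
    """
    universe = set(universe)
    query = set(query)
    if not query:
        raise ValueError("empty query set")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    if isinstance(term_map, pd.DataFrame):
        terms: dict[str, set] = {
            t: set(g) & universe
            for t, g in term_map.groupby("term_id")["gene_id"]
        }
    else:
        terms = {t: set(g) & universe for t, g in term_map.items()}
    N, n = len(universe), len(query)
    rows = []
    for term, members in sorted(terms.items()):
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "p"])
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def variant_density_comparison(effects: pd.DataFrame, aseg_set: Iterable[str],
                               all_genes: Sequence[str], n_sim: int = 1000,
                               seed: int | None = None,
                               rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Are ASEGs carrying more variants of each impact than random genes?

    ``effects`` is the variant-effect table (columns gene_id, impact;
    gene_id may be NA for intergenic variants).  For each impact
    category the observed count of variants on ASEG genes is compared
    with the counts on |ASEG|-sized gene sets resampled from
    ``all_genes`` (n_sim permutations); p = (1 + #{perm >= obs}) /
    (n_sim + 1).  The reported proportion is ASEG variants over ALL
    variants of the category, the genome-wide fraction.
    """
    aseg_set = set(aseg_set)
    if not aseg_set:
        raise ValueError("empty ASEG set")
    all_genes = list(all_genes)
    if rng is None:
        rng = np.random.default_rng(seed)

    per_gene = (effects.dropna(subset=["gene_id"])
                .groupby(["gene_id", "impact"]).size().unstack(fill_value=0)
                .reindex(columns=IMPACTS, fill_value=0)
                .reindex(all_genes, fill_value=0))
    counts = per_gene.to_numpy()
    totals = effects.groupby("impact").size().reindex(IMPACTS, fill_value=0)

    in_aseg = np.array([g in aseg_set for g in all_genes])
    observed = counts[in_aseg].sum(axis=0)

    k = int(in_aseg.sum())
    perm = np.zeros((n_sim, len(IMPACTS)), dtype=np.int64)
    for i in range(n_sim):
        pick = rng.choice(len(all_genes), size=k, replace=False)
        perm[i] = counts[pick].sum(axis=0)
    rows = []
    for j, impact in enumerate(IMPACTS):
        tot = int(totals[impact])
        prop = observed[j] / tot if tot else np.nan
        p = (1 + int((perm[:, j] >= observed[j]).sum())) / (n_sim + 1)
        rows.append((impact, int(observed[j]), tot, prop, p))
    return pd.DataFrame(rows, columns=["impact", "variants_on_asegs",
                                       "variants_genomewide", "proportion", "p"])
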