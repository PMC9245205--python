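"""Allele-specific expression: gene-level haplotypic counting from
per-SNP parental-allele counts, a per-gene NB GLM allelic-imbalance
test, and cross-tissue ASEG pattern classification.

An informative SNP is homozygous for different alleles in the two
parents, so every hybrid read covering it can be assigned to the
maternal or paternal haplotype.  Gene-level maternal/paternal counts
are the sums over the informative SNPs in a gene's exons.  Imbalance is
tested per gene and tissue with an NB GLM (log link) on the 2 x
replicates counts, design = replicate factor + allele factor, Wald test
on the allele coefficient, BH adjustment within tissue; genes with
adjusted p <= 0.05 are ASEGs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from statsmodels.stats.multitest import multipletests

from ._glm import nb_irls, wald_pvalues
from .io import GeneModel

LN2 = np.log(2.0)

ASE_COLS = ["gene_id", "tissue", "log2_ratio", "p", "p_adj", "is_aseg", "direction"]
PATTERNS = ("consistent_maternal", "consistent_paternal", "shift_direction")


def aggregate_haplotype_counts(
    per_snp_counts: pd.DataFrame,
    phased_snps: pd.DataFrame,
    gene_models: list[GeneModel],
    sample_meta: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Sum per-SNP allelic counts to gene level over exonic SNPs.

    Parameters
    ----------
    per_snp_counts : columns (chrom, pos, sample, allele, count).
    phased_snps : columns (chrom, pos, maternal_allele, paternal_allele) —
        the parent-distinguishing homozygous SNPs.
    gene_models : exon intervals define SNP-to-gene assignment; a SNP in
        the exons of several genes contributes to each and sets the
        ``multi_gene`` flag.
    sample_meta : indexed by sample id with columns (tissue, replicate).

    Returns the allelic-counts table (gene_id, tissue, replicate,
    maternal_count, paternal_count, multi_gene) and a QC dict with the
    number of count rows whose allele matched neither parent.
    """
    trees: dict[str, IntervalTree] = {}
    for g in gene_models:
        t = trees.setdefault(g.chrom, IntervalTree())
        for s, e in g.exons:
            t.addi(s, e + 1, g.gene_id)  # tree is half-open

    phase = {(r.chrom, r.pos): (r.maternal_allele, r.paternal_allele)
             for r in phased_snps.itertuples(index=False)}

    sums: dict[tuple, np.ndarray] = {}
    multi: set[str] = set()
    unmatched = 0
    for row in per_snp_counts.itertuples(index=False):
        key = (row.chrom, row.pos)
        if key not in phase:
            unmatched += int(row.count)
            continue
        mat, pat = phase[key]
        if row.allele == mat:
            col = 0
        elif row.allele == pat:
            col = 1
        else:
            unmatched += int(row.count)
            continue
        hits = trees.get(row.chrom, IntervalTree())[row.pos]
        gene_ids = sorted(h.data for h in hits)
        if len(gene_ids) > 1:
            multi.update(gene_ids)
        tissue = sample_meta.loc[row.sample, "tissue"]
        rep = sample_meta.loc[row.sample, "replicate"]
        for gid in gene_ids:
            acc = sums.setdefault((gid, tissue, rep), np.zeros(2, dtype=np.int64))
            acc[col] += int(row.count)

    rows = [(gid, tis, rep, int(v[0]), int(v[1]), gid in multi)
            for (gid, tis, rep), v in sorted(sums.items())]
    out = pd.DataFrame(rows, columns=["gene_id", "tissue", "replicate",
                                      "maternal_count", "paternal_count", "multi_gene"])
    return out, {"unmatched_allele_reads": unmatched}


def _mom_alpha(mat: np.ndarray, pat: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Per-gene dispersion from within-allele replicate variation."""
    alphas = []
    for arr in (mat, pat):
        mu = arr.mean(axis=1)
        s2 = arr.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(mu > 0, (s2 - mu) / np.maximum(mu, 1e-12) ** 2, 0.0)
        alphas.append(np.maximum(a, 0.0))
    return np.maximum((alphas[0] + alphas[1]) / 2.0, floor)


def ase_test(allelic: pd.DataFrame, tissue: str, min_depth: int = 10,
             padj_threshold: float = 0.05) -> pd.DataFrame:
    """Test allelic imbalance for every gene of one tissue.

    Genes whose summed allelic depth across replicates is below
    ``min_depth`` are reported untested (p = NA, never an ASEG).
    """
    sub = allelic[allelic["tissue"] == tissue]
    if sub.empty:
        raise ValueError(f"no allelic counts for tissue {tissue!r}")
    wide_m = sub.pivot_table(index="gene_id", columns="replicate",
                             values="maternal_count", aggfunc="sum").fillna(0)
    wide_p = sub.pivot_table(index="gene_id", columns="replicate",
                             values="paternal_count", aggfunc="sum").fillna(0)
    if wide_m.shape[1] < 2:
        raise ValueError("allelic test needs >= 2 replicates")
    genes = wide_m.index
    mat = wide_m.to_numpy(dtype=float)
    pat = wide_p.to_numpy(dtype=float)
    n_rep = mat.shape[1]
    total = mat.sum(axis=1) + pat.sum(axis=1)
    testable = total >= min_depth

    # observations ordered maternal reps then paternal reps;
    # design: intercept + replicate dummies + allele indicator (maternal=1)
    y = np.concatenate([mat, pat], axis=1)
    n_obs = 2 * n_rep
    X = np.zeros((n_obs, 1 + (n_rep - 1) + 1))
    X[:, 0] = 1.0
    for r in range(1, n_rep):
        X[r, r] = 1.0
        X[n_rep + r, r] = 1.0
    X[:n_rep, -1] = 1.0

    alpha = _mom_alpha(mat, pat)
    beta_allele = np.full(len(genes), np.nan)
    se_allele = np.full(len(genes), np.nan)
    if testable.any():
        fit = nb_irls(y[testable], X, alpha[testable])
        idx = np.where(testable)[0]
        good = fit["converged"]
        beta_allele[idx[good]] = fit["beta"][good, -1]
        se_allele[idx[good]] = fit["se"][good, -1]

    log2_ratio = beta_allele / LN2
    p = np.full(len(genes), np.nan)
    ok = np.isfinite(beta_allele) & (se_allele > 0)
    p[ok] = wald_pvalues(beta_allele[ok], se_allele[ok])
    exact0 = ok & (np.abs(beta_allele) < 1e-12)
    log2_ratio[exact0] = 0.0
    p[exact0] = 1.0

    p_adj = np.full(len(genes), np.nan)
    if ok.any():
        p_adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    is_aseg = ok & (p_adj <= padj_threshold)
    direction = np.where(~is_aseg, "none",
                         np.where(mat.sum(axis=1) > pat.sum(axis=1),
                                  "maternal", "paternal"))
    return pd.DataFrame({
        "gene_id": genes, "tissue": tissue, "log2_ratio": log2_ratio,
        "p": p, "p_adj": p_adj, "is_aseg": is_aseg, "direction": direction,
    }, columns=ASE_COLS).reset_index(drop=True)


def classify_aseg_patterns(results_t1: pd.DataFrame,
                           results_t2: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Classify genes that are ASEGs in BOTH tissues.

    Same biased parent in both tissues -> consistent_maternal /
    consistent_paternal; opposite parents -> shift_direction.  Genes
    significant in only one tissue are excluded from the pattern counts.
    """
    d1 = results_t1[results_t1["is_aseg"]].set_index("gene_id")["direction"]
    d2 = results_t2[results_t2["is_aseg"]].set_index("gene_id")["direction"]
    shared = sorted(set(d1.index) & set(d2.index))
    rows = []
    for g in shared:
        if d1[g] == d2[g]:
            rows.append((g, f"consistent_{d1[g]}"))
        else:
            rows.append((g, "shift_direction"))
    table = pd.DataFrame(rows, columns=["gene_id", "pattern"])
    counts = (table["pattern"].value_counts() if len(table) else pd.Series(dtype=int))
    counts = counts.reindex(PATTERNS, fill_value=0).astype(int)
    counts.name = "n_genes"
    return table, counts
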