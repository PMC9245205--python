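"""Counts-level differential expression: active-gene calling,
median-of-ratios normalization, method-of-moments NB dispersion with
trend shrinkage, and a two-group NB Wald test with BH adjustment.

This is a deliberately minimal NB pipeline: no fold-change shrinkage,
no outlier refitting, no independent filtering.  A gene is a DEG when
FDR <= 0.01 and |log2FC| >= 1 (both thresholds configurable).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._glm import nb_irls, wald_pvalues
from .io import CountsMatrix

LN2 = np.log(2.0)

DE_COLS = ["gene_id", "base_mean_a", "base_mean_b", "log2fc", "stat", "p", "fdr",
           "is_deg", "direction"]


def call_active_genes(counts: CountsMatrix, group: Sequence[str],
                      min_reads: int = 2, min_reps: int = 2) -> set[str]:
    """Genes covered by >= min_reads raw reads in >= min_reps replicates.

    ``group`` is the list of replicate sample ids of one accession/tissue.
    """
    if len(group) < 2:
        raise ValueError("active-gene calling needs >= 2 replicates")
    sub = counts.counts[list(group)]
    ok = (sub >= min_reads).sum(axis=1) >= min_reps
    return set(sub.index[ok])


def size_factors(counts: CountsMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Reference genes are those with nonzero counts in every sample; each
    sample's factor is the median ratio of its counts to the per-gene
    geometric means over those genes.
    """
    mat = counts.counts if isinstance(counts, CountsMatrix) else counts
    arr = mat.to_numpy(dtype=float)
    ref = (arr > 0).all(axis=1)
    if not ref.any():
        raise ValueError("no gene has nonzero counts in all samples")
    logs = np.log(arr[ref])
    geo = logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs - geo, axis=0))
    return pd.Series(sf, index=mat.columns, name="size_factor")


def normalize(counts: CountsMatrix, sf: pd.Series | None = None) -> pd.DataFrame:
    if sf is None:
        sf = size_factors(counts)
    return counts.counts / sf


def estimate_dispersion(counts: CountsMatrix, groups: Sequence[Sequence[str]],
                        sf: pd.Series | None = None,
                        shrink_weight: float = 0.5) -> pd.Series:
    """Per-gene NB dispersion alpha (Var = mu + alpha mu^2).

    Raw estimate: method of moments (s^2 - mean)/mean^2 within each
    replicate group on normalized counts, pooled across groups with
    degrees-of-freedom weights and clamped at 0.  The raw values are then
    shrunk ``shrink_weight``/(1-shrink_weight) toward a mean-dispersion
    trend alpha(mu) = a0/mu + a1 fitted by least squares over genes.
    All-zero genes get NaN and are excluded from testing.
    """
    norm = normalize(counts, sf)
    num = np.zeros(len(norm))
    dof = 0.0
    overall = norm[[s for g in groups for s in g]].mean(axis=1).to_numpy()
    for g in groups:
        if len(g) < 2:
            raise ValueError("dispersion estimation needs >= 2 replicates per group")
        sub = norm[list(g)].to_numpy()
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(mu > 0, (s2 - mu) / np.maximum(mu, 1e-12) ** 2, np.nan)
        w = len(g) - 1
        num += np.nan_to_num(raw) * w
        dof += w
    alpha_raw = np.maximum(num / dof, 0.0)
    alpha_raw[overall <= 0] = np.nan

    ok = np.isfinite(alpha_raw) & (overall > 0)
    # trend alpha(mu) = a0/mu + a1, least squares over genes with data
    A = np.column_stack([1.0 / overall[ok], np.ones(ok.sum())])
    coef, *_ = np.linalg.lstsq(A, alpha_raw[ok], rcond=None)
    with np.errstate(divide="ignore"):
        trend = np.maximum(coef[0] / overall + coef[1], 0.0)
    alpha = shrink_weight * alpha_raw + (1.0 - shrink_weight) * trend
    alpha = np.where(np.isfinite(alpha_raw), np.maximum(alpha, 0.0), np.nan)
    return pd.Series(alpha, index=norm.index, name="alpha")


def nb_wald_test(counts: CountsMatrix, group_a: Sequence[str], group_b: Sequence[str],
                 sf: pd.Series | None = None, alpha: pd.Series | None = None,
                 fdr_threshold: float = 0.01, lfc_threshold: float = 1.0) -> pd.DataFrame:
    """Two-group NB Wald test of group B vs group A (log2FC > 0 = higher in B).

    Per gene an NB GLM with log link and log size-factor offsets is fit
    by IRLS; the Wald statistic is the group coefficient over its
    standard error, with a two-sided normal p-value and BH adjustment
    over the tested genes.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need >= 2 replicates")
    if sf is None:
        sf = size_factors(counts)
    if alpha is None:
        alpha = estimate_dispersion(counts, [group_a, group_b], sf=sf)

    ids = group_a + group_b
    y = counts.counts[ids].to_numpy(dtype=float)
    offs = np.log(sf[ids].to_numpy())
    X = np.column_stack([np.ones(len(ids)),
                         np.r_[np.zeros(len(group_a)), np.ones(len(group_b))]])

    genes = counts.counts.index
    testable = alpha.reindex(genes).notna().to_numpy() & (y.sum(axis=1) > 0)
    a = np.nan_to_num(alpha.reindex(genes).to_numpy())

    beta = np.full((len(genes), 2), np.nan)
    se = np.full((len(genes), 2), np.nan)
    if testable.any():
        fit = nb_irls(y[testable], X, a[testable], offset=offs)
        beta[testable] = fit["beta"]
        se[testable] = fit["se"]
        if not fit["converged"].all():
            n_bad = int((~fit["converged"]).sum())
            warnings.warn(f"{n_bad} gene fits did not converge; p set to NA",
                          stacklevel=2)
            bad = np.where(testable)[0][~fit["converged"]]
            beta[bad] = np.nan
            se[bad] = np.nan

    log2fc = beta[:, 1] / LN2
    with np.errstate(invalid="ignore"):
        stat = np.where(se[:, 1] > 0, beta[:, 1] / se[:, 1], 0.0)
    stat = np.where(np.isfinite(beta[:, 1]), stat, np.nan)
    p = np.full(len(genes), np.nan)
    ok = np.isfinite(stat)
    p[ok] = wald_pvalues(beta[ok, 1], se[ok, 1])
    # exact-null guard: literally identical groups give beta ~ 0 to
    # machine precision; snap to the symmetric answer
    exact0 = ok & (np.abs(beta[:, 1]) < 1e-12)
    log2fc[exact0] = 0.0
    stat[exact0] = 0.0
    p[exact0] = 1.0

    fdr = np.full(len(genes), np.nan)
    if ok.any():
        fdr[ok] = multipletests(p[ok], method="fdr_bh")[1]

    norm = counts.counts[ids] / sf[ids]
    base_a = norm[group_a].mean(axis=1).to_numpy()
    base_b = norm[group_b].mean(axis=1).to_numpy()
    is_deg = ok & (fdr <= fdr_threshold) & (np.abs(log2fc) >= lfc_threshold)
    direction = np.where(~is_deg, "ns", np.where(log2fc > 0, "up", "down"))
    return pd.DataFrame({
        "gene_id": genes, "base_mean_a": base_a, "base_mean_b": base_b,
        "log2fc": log2fc, "stat": stat, "p": p, "fdr": fdr,
        "is_deg": is_deg, "direction": direction,
    }, columns=DE_COLS)


def sample_correlation(counts: CountsMatrix, sf: pd.Series | None = None) -> pd.DataFrame:
    """Pairwise R^2 of log2(normalized count + 1) between samples.

    Each pair is computed over the genes detected (raw count >= 1) in at
    least one of the two samples; a zero-variance sample gives NaN.
    """
    if counts.counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    norm = normalize(counts, sf)
    logn = np.log2(norm + 1.0)
    raw = counts.counts.to_numpy()
    ids = list(counts.counts.columns)
    n = len(ids)
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            mask = (raw[:, i] >= 1) | (raw[:, j] >= 1)
            if mask.sum() < 2:
                continue
            x = logn.iloc[:, i].to_numpy()[mask]
            yv = logn.iloc[:, j].to_numpy()[mask]
            if x.std() == 0 or yv.std() == 0:
                continue
            r = np.corrcoef(x, yv)[0, 1]
            out[i, j] = out[j, i] = r * r
    return pd.DataFrame(out, index=ids, columns=ids)
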