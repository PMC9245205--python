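"""Additive/dominance effects and the Hp inheritance-mode classifier.

For a gene with mean normalized expression p1 (mother), p2 (father) and
f1 (hybrid), the additive effect is a = |p1 - p2| / 2 and the dominance
effect is d = f1 - (p1 + p2) / 2 (the departure from the mid-parent
value).  The ratio Hp = d / a classifies the inheritance mode:

    additive            -0.2 < Hp <= 0.2
    partial dominance   -0.8 < Hp <= -0.2  or  0.2 < Hp <= 0.8
    dominance           -1.2 < Hp <= -0.8  or  0.8 < Hp <= 1.2
    over-dominance       Hp <= -1.2        or  Hp > 1.2

The boundaries are half-open exactly as written above, including the
asymmetric over-dominance pair (closed at -1.2, open at 1.2).  When the
parents are equal (a = 0) and the hybrid differs, Hp is +/-inf with the
sign of d and the gene is over-dominant (the hybrid lies outside the
parental range by definition); a = d = 0 gives Hp = 0, additive.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

CATEGORIES = ("over_dominance", "dominance", "partial_dominance", "additive")

#: Canonical column order of the per-gene dominance table.
RECORD_COLS = ["gene_id", "tissue", "p1", "p2", "f1", "a_effect", "d_effect", "hp", "category"]


def hp_statistic(p1: float, p2: float, f1: float) -> tuple[float, float, float]:
    """Return (a_effect, d_effect, hp) for one gene.

    hp is +/-inf (sign of d) when a = 0 and d != 0, and 0 when both are 0.
    """
    if p1 < 0 or p2 < 0 or f1 < 0:
        raise ValueError("mean expression values must be non-negative")
    a = abs(p1 - p2) / 2.0
    d = f1 - (p1 + p2) / 2.0
    if a > 0:
        hp = d / a
    elif d != 0:
        hp = math.copysign(math.inf, d)
    else:
        hp = 0.0
    return a, d, hp


def classify_dominance(hp: float) -> str:
    """Map an Hp value (extended real) to its inheritance-mode category."""
    if isinstance(hp, float) and math.isnan(hp):
        raise ValueError("Hp is NaN")
    if hp <= -1.2 or hp > 1.2:
        return "over_dominance"
    if -1.2 < hp <= -0.8 or 0.8 < hp <= 1.2:
        return "dominance"
    if -0.8 < hp <= -0.2 or 0.2 < hp <= 0.8:
        return "partial_dominance"
    return "additive"  # -0.2 < hp <= 0.2


def dghp_gene_set(de_vs_mother: pd.DataFrame, de_vs_father: pd.DataFrame,
                  mode: str = "union") -> set[str]:
    """Genes differentially expressed between hybrid and its parents.

    ``mode='union'`` (default) takes DEGs from either hybrid-vs-parent
    contrast; ``'intersection'`` requires both.
    """
    a = set(de_vs_mother.loc[de_vs_mother["is_deg"], "gene_id"])
    b = set(de_vs_father.loc[de_vs_father["is_deg"], "gene_id"])
    if mode == "union":
        return a | b
    if mode == "intersection":
        return a & b
    raise ValueError(f"unknown DGhp mode {mode!r}")


def classify_dghp(counts, de_vs_mother: pd.DataFrame, de_vs_father: pd.DataFrame,
                  tissue: str, size_factors: pd.Series | None = None,
                  mode: str = "union") -> tuple[pd.DataFrame, pd.Series]:
    """Hp-classify every DGhp gene of one tissue.

    p1/p2/f1 are arithmetic means of size-factor-normalized counts over
    the biological replicates of the tissue.  Returns the per-gene table
    and the category percentages (over the DGhp set).
    """
    from . import diffexpr

    genes = sorted(dghp_gene_set(de_vs_mother, de_vs_father, mode=mode))
    if not genes:
        import warnings

        warnings.warn(f"empty DGhp set for tissue {tissue!r}", stacklevel=2)
    if size_factors is None:
        size_factors = diffexpr.size_factors(counts)
    norm = counts.counts / size_factors

    def group_mean(role: str) -> pd.Series:
        ids = counts.sample_ids(role=role, tissue=tissue)
        if not ids:
            raise ValueError(f"no {role} samples in tissue {tissue!r}")
        return norm[ids].mean(axis=1)

    m1, m2, mf = group_mean("maternal"), group_mean("paternal"), group_mean("hybrid")
    rows = []
    for g in genes:
        a, d, hp = hp_statistic(m1[g], m2[g], mf[g])
        rows.append((g, tissue, m1[g], m2[g], mf[g], a, d, hp, classify_dominance(hp)))
    table = pd.DataFrame(rows, columns=RECORD_COLS)
    if len(table):
        pct = table["category"].value_counts(normalize=True) * 100.0
    else:
        pct = pd.Series(dtype=float)
    pct = pct.reindex(CATEGORIES, fill_value=0.0)
    pct.name = "percent"
    return table, pct
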