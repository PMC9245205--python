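"""Shared fixtures: small count matrices and a hand-built two-gene
annotation playground (one gene per strand) with 20 variants covering
every consequence term."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from heteroseq.io import CountsMatrix, GeneModel, VariantRecord
from heteroseq.simdata import (
    _CDS1, _GENE_LEN, _UTR5, _gene_layout, _genomic_pos_of_cds_offset,
    _revcomp, _transcript_cds,
)


def make_counts(counts: np.ndarray, n_a: int = 3, n_b: int = 3,
                tissue: str = "leaf") -> CountsMatrix:
    """Two-group CountsMatrix (maternal group A, hybrid group B)."""
    G = counts.shape[0]
    ids = [f"g{i:04d}" for i in range(G)]
    cols = [f"A_{tissue}_{r}" for r in range(1, n_a + 1)] + \
           [f"B_{tissue}_{r}" for r in range(1, n_b + 1)]
    df = pd.DataFrame(counts, index=pd.Index(ids, name="gene_id"), columns=cols)
    meta = [(c, c[0], "maternal" if c[0] == "A" else "hybrid", tissue,
             int(c.rsplit("_", 1)[1])) for c in cols]
    samples = pd.DataFrame(meta, columns=["sample_id", "accession", "role",
                                          "tissue", "replicate"]).set_index("sample_id")
    return CountsMatrix(counts=df, samples=samples)


@pytest.fixture(scope="session")
def annotation_fixture():
    """Two genes (plus/minus strand) on one synthetic chromosome, with a
    curated list of (variant, expected consequence) pairs spanning the
    full consequence ontology."""
    cds = _transcript_cds()  # ATG + TGG CTG GGA AAA ... + TAA
    utr5, utr3 = "ACGTACGTACGTACGTACGTACGTACGTAC", "TTGACCTGATCGATCGATCGATCGATCGAT"
    intron = "GT" + "C" * 96 + "AG"
    segment = utr5 + cds[:_CDS1] + intron + cds[_CDS1:] + utr3

    g0p, g0m = 10001, 16001
    L = 22000
    chrom = list("ACGT" * (L // 4))
    chrom[g0p - 1: g0p - 1 + _GENE_LEN] = list(segment)
    chrom[g0m - 1: g0m - 1 + _GENE_LEN] = list(_revcomp(segment))
    genome = {"chrT": "".join(chrom)}

    exP, cdP = _gene_layout(g0p, "+")
    exM, cdM = _gene_layout(g0m, "-")
    gp = GeneModel("GP", "chrT", "+", exP, cdP)
    gm = GeneModel("GM", "chrT", "-", exM, cdM)

    def at(gene, off):  # genomic position of transcript CDS offset
        return _genomic_pos_of_cds_offset(gene, off)

    seq = genome["chrT"]

    def snp(pos, alt, gene=None):
        return VariantRecord("chrT", pos, seq[pos - 1], alt, variant_id=f"v{pos}")

    variants = [
        # --- plus-strand gene ---
        (snp(at(gp, 5), "A"), "stop_gained"),          # TGG codon1 -> TGA
        (snp(at(gp, 3 * 99 + 1), "C"), "stop_lost"),   # TAA -> TCA
        (snp(at(gp, 0), "G"), "start_lost"),           # ATG -> GTG
        (VariantRecord("chrT", at(gp, 9), seq[at(gp, 9) - 1: at(gp, 9) + 2],
                       seq[at(gp, 9) - 1], variant_id="del2p"), "frameshift"),
        (snp(gp.introns()[0][0], "A"), "splice_donor"),
        (snp(gp.introns()[0][1], "C"), "splice_acceptor"),
        (VariantRecord("chrT", at(gp, 12), seq[at(gp, 12) - 1: at(gp, 12) + 3],
                       seq[at(gp, 12) - 1], variant_id="del3p"), "inframe_indel"),
        (snp(at(gp, 6), "A"), "missense"),             # CTG -> ATG (Leu->Met)
        (snp(at(gp, 11), "G"), "synonymous"),          # GGA -> GGG
        (snp(at(gp, 3 * 99 + 2), "G"), "stop_retained"),  # TAA -> TAG
        (snp(gp.introns()[0][0] + 40, "A" if seq[gp.introns()[0][0] + 39] != "A"
             else "T"), "intron"),
        (snp(g0p + 5, "A" if seq[g0p + 4] != "A" else "T"), "utr"),
        (snp(g0p - 1200, "A" if seq[g0p - 1201] != "A" else "T"), "upstream"),
        (snp(g0p + _GENE_LEN + 700, "A" if seq[g0p + _GENE_LEN + 699] != "A"
             else "T"), "downstream"),
        (snp(100, "A" if seq[99] != "A" else "T"), "intergenic"),
        # --- minus-strand gene (transcript-sense edits complemented) ---
        (snp(at(gm, 5), "T"), "stop_gained"),          # G->A on transcript
        (snp(at(gm, 6), "T"), "missense"),             # C->A on transcript
        (snp(at(gm, 11), "C"), "synonymous"),          # A->G on transcript
        (VariantRecord("chrT", at(gm, 20) - 1, seq[at(gm, 20) - 2],
                       seq[at(gm, 20) - 2] + "T", variant_id="insm"), "frameshift"),
        (snp(gm.introns()[0][1], "A" if seq[gm.introns()[0][1] - 1] != "A" else "T"),
         "splice_donor"),
    ]
    return {"genes": [gp, gm], "genome": genome, "variants": variants}
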