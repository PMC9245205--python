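"""Variant-effect classification and hard filtering.

Variants are classified against gene models into a minimal consequence
ontology and the four standard impact tiers:

    HIGH      stop_gained, stop_lost, start_lost, frameshift,
              splice_acceptor, splice_donor
    MODERATE  inframe_indel, missense
    LOW       synonymous, stop_retained
    MODIFIER  intron, utr, upstream, downstream, intergenic

One effect is reported per variant: the most severe consequence over
all overlapping gene features (HIGH > MODERATE > LOW > MODIFIER, ties
broken by the order above).  Splice sites are the first/last two
intronic bases; upstream/downstream windows are 5 kb.

Hard filtering applies the GATK-style criteria
SNP:   QUAL < 30, QD < 2, SOR > 3, FS > 60, MQ < 40,
       MQRankSum < -12.5, ReadPosRankSum < -8
indel: QUAL < 30, QD < 2, FS > 200, MQ < 40, ReadPosRankSum < -20
The rank-sum thresholds follow the documented negative-value convention
(positive thresholds would discard nearly every variant); pass
``rank_sum_sign_fix=False`` to apply them verbatim as positive bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .io import GeneModel, VariantRecord

CONSEQUENCES = (
    "stop_gained", "stop_lost", "start_lost", "frameshift",
    "splice_acceptor", "splice_donor", "inframe_indel", "missense",
    "synonymous", "stop_retained", "intron", "utr", "upstream",
    "downstream", "intergenic",
)
_RANK = {c: i for i, c in enumerate(CONSEQUENCES)}

IMPACT_OF = {
    "stop_gained": "HIGH", "stop_lost": "HIGH", "start_lost": "HIGH",
    "frameshift": "HIGH", "splice_acceptor": "HIGH", "splice_donor": "HIGH",
    "inframe_indel": "MODERATE", "missense": "MODERATE",
    "synonymous": "LOW", "stop_retained": "LOW",
    "intron": "MODIFIER", "utr": "MODIFIER", "upstream": "MODIFIER",
    "downstream": "MODIFIER", "intergenic": "MODIFIER",
}

FLANK = 5000  # upstream/downstream window, bp
SPLICE = 2    # intronic bases on each side of an exon


@dataclass
class VariantEffect:
    variant: VariantRecord
    gene_id: str | None
    consequence: str
    impact: str = ""

    def __post_init__(self) -> None:
        if not self.impact:
            self.impact = IMPACT_OF[self.consequence]


@dataclass
class FilterVerdict:
    variant: VariantRecord
    passed: bool
    failed_criteria: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# hard filters
# ---------------------------------------------------------------------------

_SNP_RULES = [("QUAL", "lt", 30.0), ("QD", "lt", 2.0), ("SOR", "gt", 3.0),
              ("FS", "gt", 60.0), ("MQ", "lt", 40.0),
              ("MQRankSum", "lt", 12.5), ("ReadPosRankSum", "lt", 8.0)]
_INDEL_RULES = [("QUAL", "lt", 30.0), ("QD", "lt", 2.0), ("FS", "gt", 200.0),
                ("MQ", "lt", 40.0), ("ReadPosRankSum", "lt", 20.0)]
_RANKSUM_KEYS = {"MQRankSum", "ReadPosRankSum"}


def filter_variants(records: Iterable[VariantRecord],
                    rank_sum_sign_fix: bool = True) -> list[FilterVerdict]:
    """Apply the SNP/indel hard-filter criteria; one verdict per record.

    A record fails if any criterion of its class holds; missing metrics
    skip their criterion.  Records that are neither SNP nor indel
    (same-length multi-base substitutions) are passed through with a
    warning.
    """
    out = []
    for rec in records:
        if rec.is_snp:
            rules = _SNP_RULES
        elif rec.is_indel:
            rules = _INDEL_RULES
        else:
            warnings.warn(f"{rec.chrom}:{rec.pos} complex record passed through",
                          stacklevel=2)
            out.append(FilterVerdict(rec, True, []))
            continue
        failed = []
        for key, op, thr in rules:
            val = rec.qual if key == "QUAL" else rec.info.get(key)
            if val is None:
                continue
            if rank_sum_sign_fix and key in _RANKSUM_KEYS:
                thr = -thr
            if (op == "lt" and val < thr) or (op == "gt" and val > thr):
                failed.append(f"{key}{'<' if op == 'lt' else '>'}{thr:g}")
        out.append(FilterVerdict(rec, not failed, failed))
    return out


# ---------------------------------------------------------------------------
# consequence classification
# ---------------------------------------------------------------------------


def _affected_interval(v: VariantRecord) -> tuple[int, int]:
    """1-based inclusive reference interval actually altered."""
    if v.is_snp or len(v.ref) == len(v.alt):
        return v.pos, v.end
    if len(v.ref) > len(v.alt):  # deletion: anchor base unchanged
        return v.pos + len(v.alt), v.end
    return v.pos, v.pos + 1  # insertion between pos and pos+1


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _cds_offset(gene: GeneModel, pos: int) -> int | None:
    """Transcript-sense 0-based offset of a genomic position in the CDS."""
    segs = gene.cds if gene.strand == "+" else list(reversed(gene.cds))
    off = 0
    for s, e, _ in segs:
        if s <= pos <= e:
            return off + (pos - s if gene.strand == "+" else e - pos)
        off += e - s + 1
    return None


def _cds_sequence(gene: GeneModel, genome: Mapping[str, str]) -> str:
    chrom = genome[gene.chrom]
    seq = "".join(chrom[s - 1:e] for s, e, _ in gene.cds)
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _coding_snp(gene: GeneModel, v: VariantRecord, genome: Mapping[str, str]) -> str | None:
    off = _cds_offset(gene, v.pos)
    if off is None:
        return None
    off -= gene.first_phase
    if off < 0:
        return None
    cds = _cds_sequence(gene, genome)[gene.first_phase:]
    codon_idx, within = divmod(off, 3)
    codon = cds[codon_idx * 3: codon_idx * 3 + 3]
    if len(codon) < 3:
        return None
    ref_b, alt_b = v.ref, v.alt
    if gene.strand == "-":
        ref_b = str(Seq(ref_b).reverse_complement())
        alt_b = str(Seq(alt_b).reverse_complement())
    if codon[within] != ref_b:
        warnings.warn(
            f"{v.chrom}:{v.pos} REF {v.ref!r} does not match the genome; "
            "classifying against the stated REF", stacklevel=2)
        codon = codon[:within] + ref_b + codon[within + 1:]
    alt_codon = codon[:within] + alt_b + codon[within + 1:]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if codon_idx == 0 and codon == "ATG" and alt_codon != "ATG":
        return "start_lost"
    if ref_aa == "*":
        return "stop_retained" if alt_aa == "*" else "stop_lost"
    if alt_aa == "*":
        return "stop_gained"
    return "synonymous" if ref_aa == alt_aa else "missense"


def _gene_consequence(gene: GeneModel, v: VariantRecord,
                      genome: Mapping[str, str]) -> str | None:
    aff = _affected_interval(v)
    span = (gene.start, gene.end)
    if _overlaps(aff, span):
        in_cds = any(_overlaps(aff, (s, e)) for s, e, _ in gene.cds)
        if in_cds and gene.valid_cds:
            if v.is_indel:
                shift = abs(len(v.ref) - len(v.alt)) % 3
                return "frameshift" if shift else "inframe_indel"
            if v.is_snp:
                call = _coding_snp(gene, v, genome)
                if call is not None:
                    return call
        for s, e in gene.introns():
            donor = (s, s + SPLICE - 1) if gene.strand == "+" else (e - SPLICE + 1, e)
            acceptor = (e - SPLICE + 1, e) if gene.strand == "+" else (s, s + SPLICE - 1)
            if _overlaps(aff, donor):
                return "splice_donor"
            if _overlaps(aff, acceptor):
                return "splice_acceptor"
            if _overlaps(aff, (s, e)):
                return "intron"
        if any(_overlaps(aff, x) for x in gene.exons):
            return "utr"
        return "intron"
    # flanks, strand-aware
    if gene.strand == "+":
        up = (gene.start - FLANK, gene.start - 1)
        down = (gene.end + 1, gene.end + FLANK)
    else:
        up = (gene.end + 1, gene.end + FLANK)
        down = (gene.start - FLANK, gene.start - 1)
    if _overlaps(aff, up):
        return "upstream"
    if _overlaps(aff, down):
        return "downstream"
    return None


def classify_variant_effect(variant: VariantRecord, gene_models: Sequence[GeneModel],
                            genome: Mapping[str, str]) -> VariantEffect:
    """Most severe consequence of one variant over all overlapping genes."""
    if variant.chrom not in genome:
        warnings.warn(f"variant chromosome {variant.chrom!r} not in genome; "
                      "treated as intergenic", stacklevel=2)
        return VariantEffect(variant, None, "intergenic")
    best: tuple[int, str, str] | None = None
    for gene in gene_models:
        if gene.chrom != variant.chrom:
            continue
        call = _gene_consequence(gene, variant, genome)
        if call is None:
            continue
        key = (_RANK[call], gene.gene_id)
        if best is None or key < (best[0], best[2]):
            best = (_RANK[call], call, gene.gene_id)
    if best is None:
        return VariantEffect(variant, None, "intergenic")
    return VariantEffect(variant, best[2], best[1])


def classify_variants(variants: Iterable[VariantRecord],
                      gene_models: Sequence[GeneModel],
                      genome: Mapping[str, str]) -> list[VariantEffect]:
    return [classify_variant_effect(v, gene_models, genome) for v in variants]


def effects_to_frame(effects: Sequence[VariantEffect]) -> pd.DataFrame:
    rows = [(e.variant.chrom, e.variant.pos, e.variant.ref, e.variant.alt,
             e.variant.variant_id, e.gene_id, e.consequence, e.impact)
            for e in effects]
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "variant_id",
                                       "gene_id", "consequence", "impact"])


def effects_by_gene(effects: Sequence[VariantEffect] | pd.DataFrame) -> pd.DataFrame:
    """Per-gene tallies of variants by impact category (genic variants only)."""
    df = effects if isinstance(effects, pd.DataFrame) else effects_to_frame(effects)
    if df.empty:
        return pd.DataFrame(columns=["HIGH", "MODERATE", "LOW", "MODIFIER"])
    return (df.dropna(subset=["gene_id"])
            .groupby(["gene_id", "impact"]).size().unstack(fill_value=0)
            .reindex(columns=["HIGH", "MODERATE", "LOW", "MODIFIER"], fill_value=0))
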