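"""Synthetic data with planted ground truth.

Generates everything the pipeline consumes — trio count matrices,
per-gene allelic counts, gene models + genome + variants, and gene-term
maps — with the statistical structure the analysis assumes, plus a
truth table recording what was planted.  The truth table is written as
a separate TSV that the pipeline proper never reads; only tests use it.

Counts are negative binomial with Var = mu + alpha*mu^2 (dispersion
alpha shared across genes).  Genes planted in an Hp category get parent
means (p1, p2) at a fixed ratio and a hybrid mean placed strictly
inside the category's Hp interval (margin >= 0.1 from each endpoint),
with the hybrid at least 2**lfc_magnitude-fold from one parent;
non-differential genes share one mean across all three accessions.
Allelic totals are Poisson and maternal counts binomial with
pi = ase_fold/(1+ase_fold) for maternal-biased genes (mirrored for
paternal, 0.5 for balanced).  Variants are planted by construction:
stop-gain or frameshift for HIGH, codon-changing SNP for MODERATE,
synonymous SNP for LOW, and an intronic SNP for MODIFIER.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountsMatrix, GeneModel, VariantRecord
from . import io as hio

CATEGORIES = ("over_dominance", "dominance", "partial_dominance", "additive")
IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")

#: Relative category weights used when hp_category_fractions is not given;
#: over-dominance dominates, mirroring the observed predominance of
#: over-dominant DEGs in hybrid rice expression studies.
DEFAULT_CATEGORY_WEIGHTS = {
    "over_dominance": 0.85, "dominance": 0.05,
    "partial_dominance": 0.05, "additive": 0.05,
}


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of the synthetic study (one parent/parent/hybrid trio)."""

    seed: int = 0
    n_genes: int = 2000
    n_replicates: int = 3
    tissues: tuple[str, ...] = ("leaf", "panicle")
    mean_log_expression: float = math.log(200.0)
    sd_log_expression: float = 1.0
    dispersion: float = 0.05
    frac_de: float = 0.3
    lfc_magnitude: float = 1.0
    hp_category_fractions: dict[str, float] | None = None
    frac_ase: float = 0.2
    ase_fold: float = 4.0
    allelic_depth_mean: float = 100.0
    n_variants_per_gene: float = 2.0
    impact_category_probs: dict[str, float] = field(default_factory=lambda: {
        "HIGH": 0.1, "MODERATE": 0.2, "LOW": 0.3, "MODIFIER": 0.4})
    ase_variant_multiplier: float = 3.0
    n_terms: int = 50
    term_size_mean: float = 40.0
    genes_per_chrom: int = 100
    intergenic_gap: int = 2000

    def __post_init__(self) -> None:
        for name in ("frac_de", "frac_ase"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if self.ase_fold <= 1:
            raise ConfigurationError("ase_fold must be > 1")
        if self.allelic_depth_mean < 0:
            raise ConfigurationError("allelic_depth_mean must be >= 0")
        if not 0 < self.lfc_magnitude <= 1.2:
            raise ConfigurationError(
                "lfc_magnitude must be in (0, 1.2]: the planted-Hp construction "
                "uses a parent ratio of 2**(lfc_magnitude+1) and larger values "
                "break the hybrid-vs-parent fold-change guarantee")
        if self.hp_category_fractions is not None:
            bad = set(self.hp_category_fractions) - set(CATEGORIES)
            if bad:
                raise ConfigurationError(f"unknown Hp categories {sorted(bad)}")
            total = sum(self.hp_category_fractions.values())
            if total > 1.0 + 1e-9:
                raise ConfigurationError("hp_category_fractions sum exceeds 1")
            if any(v < 0 for v in self.hp_category_fractions.values()):
                raise ConfigurationError("hp_category_fractions must be >= 0")
        probs = self.impact_category_probs
        if set(probs) != set(IMPACTS):
            raise ConfigurationError(f"impact_category_probs must cover {IMPACTS}")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("impact_category_probs must sum to 1")

    def category_fractions(self) -> dict[str, float]:
        """Absolute fraction of genes planted in each Hp category."""
        if self.hp_category_fractions is not None:
            return dict(self.hp_category_fractions)
        return {c: self.frac_de * w for c, w in DEFAULT_CATEGORY_WEIGHTS.items()}

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator per simulation stage."""
        return np.random.default_rng([self.seed, stream])


# Planted Hp targets per category and sign.  All sit >= 0.1 inside their
# interval.  The negative over-dominance target is capped at -1.6 so the
# hybrid mean stays positive with a parent ratio of 4.
_HP_TARGETS = {
    "additive": (0.0, 0.0),
    "partial_dominance": (0.5, -0.5),
    "dominance": (1.0, -1.0),
    "over_dominance": (2.5, -1.6),
}


def planted_trio_means(base: float, category: str, sign: int,
                       parent_ratio: float) -> tuple[float, float, float, float]:
    """Noiseless (p1, p2, f1, hp) for a gene planted in ``category``.

    ``sign`` picks the positive or negative Hp target; the higher parent
    is p1 here — callers may swap parents afterwards.
    """
    hp = _HP_TARGETS[category][0 if sign >= 0 else 1]
    p1, p2 = base * parent_ratio, base
    mid = (p1 + p2) / 2.0
    a = (p1 - p2) / 2.0
    f1 = mid + hp * a
    return p1, p2, f1, hp


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if alpha <= 0:
        return rng.poisson(mu)
    n = 1.0 / alpha
    p = 1.0 / (1.0 + alpha * mu)
    return rng.negative_binomial(n, p)


def simulate_trio_counts(config: SimConfig) -> tuple[CountsMatrix, pd.DataFrame]:
    """Simulate the trio count matrix and the gene-level truth table.

    Truth columns: gene_id, tissue, de_status, hp_category ('none' for
    unplanted genes), hp_planted, p1/p2/f1 noiseless means,
    ase_direction.
    """
    rng = config.rng(1)
    G = config.n_genes
    gene_ids = [f"gene{g:05d}" for g in range(1, G + 1)]
    base = np.exp(rng.normal(config.mean_log_expression, config.sd_log_expression, G))
    ratio = 2.0 ** (config.lfc_magnitude + 1.0)

    fracs = config.category_fractions()
    labels = list(CATEGORIES) + ["none"]
    probs = [fracs.get(c, 0.0) for c in CATEGORIES]
    probs.append(max(0.0, 1.0 - sum(probs)))
    ase_labels = ["maternal", "paternal", "none"]
    ase_probs = [config.frac_ase / 2, config.frac_ase / 2, 1 - config.frac_ase]

    truth_rows = []
    means: dict[str, dict[str, np.ndarray]] = {}  # tissue -> accession -> (G,)
    for tissue in config.tissues:
        cats = rng.choice(len(labels), size=G, p=probs)
        signs = rng.choice([1, -1], size=G)
        swaps = rng.random(G) < 0.5  # which parent is the high one
        ase_dir = rng.choice(ase_labels, size=G, p=ase_probs)
        p1 = base.copy()
        p2 = base.copy()
        f1 = base.copy()
        for g in range(G):
            cat = labels[cats[g]]
            if cat == "none":
                truth_rows.append((gene_ids[g], tissue, False, "none", np.nan,
                                   base[g], base[g], base[g], ase_dir[g]))
                continue
            a1, a2, af, hp = planted_trio_means(base[g], cat, signs[g], ratio)
            if swaps[g]:
                a1, a2 = a2, a1
            p1[g], p2[g], f1[g] = a1, a2, af
            truth_rows.append((gene_ids[g], tissue, True, cat, hp, a1, a2, af,
                               ase_dir[g]))
        means[tissue] = {"P1": p1, "P2": p2, "F1": f1}

    cols = {}
    meta = []
    for tissue in config.tissues:
        for acc, role in (("P1", "maternal"), ("P2", "paternal"), ("F1", "hybrid")):
            for rep in range(1, config.n_replicates + 1):
                sid = f"{acc}_{tissue}_{rep}"
                cols[sid] = _nb_sample(rng, means[tissue][acc], config.dispersion)
                meta.append((sid, acc, role, tissue, rep))
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    samples = pd.DataFrame(meta, columns=["sample_id", "accession", "role",
                                          "tissue", "replicate"]).set_index("sample_id")
    truth = pd.DataFrame(truth_rows, columns=[
        "gene_id", "tissue", "de_status", "hp_category", "hp_planted",
        "p1", "p2", "f1", "ase_direction"])
    return CountsMatrix(counts=counts, samples=samples), truth


def simulate_allelic_counts(config: SimConfig, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-gene maternal/paternal counts for the hybrid, from the truth table.

    Total depth per gene/tissue/replicate is Poisson(allelic_depth_mean);
    the maternal share is binomial with pi set by the planted direction.
    """
    rng = config.rng(2)
    pi_m = config.ase_fold / (1.0 + config.ase_fold)
    pi_of = {"maternal": pi_m, "paternal": 1.0 - pi_m, "none": 0.5}
    rows = []
    for r in truth.itertuples(index=False):
        pi = pi_of[r.ase_direction]
        for rep in range(1, config.n_replicates + 1):
            total = rng.poisson(config.allelic_depth_mean)
            m = rng.binomial(total, pi) if total > 0 else 0
            rows.append((r.gene_id, r.tissue, rep, m, total - m))
    return pd.DataFrame(rows, columns=hio.ALLELIC_COLS)


# ---------------------------------------------------------------------------
# genome, gene models, variants
# ---------------------------------------------------------------------------

_UTR5, _CDS1, _INTRON, _CDS2, _UTR3 = 30, 120, 100, 180, 30
_GENE_LEN = _UTR5 + _CDS1 + _INTRON + _CDS2 + _UTR3
_N_CODONS = (_CDS1 + _CDS2) // 3
_MOTIF = ("TGG", "CTG", "GGA", "AAA")  # repeated between start and stop
_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _transcript_cds() -> str:
    body = [(_MOTIF[i % 4]) for i in range(_N_CODONS - 2)]
    return "ATG" + "".join(body) + "TAA"


def _gene_layout(g0: int, strand: str) -> tuple[list[tuple[int, int]], list[tuple[int, int, int]]]:
    """Exon/CDS intervals for a gene whose segment starts at 1-based g0."""
    # plus-strand block offsets within the segment
    e1 = (g0, g0 + _UTR5 + _CDS1 - 1)
    e2 = (g0 + _UTR5 + _CDS1 + _INTRON, g0 + _GENE_LEN - 1)
    c1 = (g0 + _UTR5, g0 + _UTR5 + _CDS1 - 1)
    c2 = (g0 + _UTR5 + _CDS1 + _INTRON, g0 + _GENE_LEN - _UTR3 - 1)
    if strand == "+":
        return [e1, e2], [(c1[0], c1[1], 0), (c2[0], c2[1], 0)]
    # mirror within the segment
    last = g0 + _GENE_LEN - 1

    def mir(iv: tuple[int, int]) -> tuple[int, int]:
        return (g0 + (last - iv[1]), g0 + (last - iv[0]))

    exons = sorted([mir(e1), mir(e2)])
    cds = sorted([mir(c1), mir(c2)])
    return exons, [(s, e, 0) for s, e in cds]


def _genomic_pos_of_cds_offset(gene: GeneModel, off: int) -> int:
    """Inverse of the transcript-offset mapping (0-based CDS offset)."""
    segs = gene.cds if gene.strand == "+" else list(reversed(gene.cds))
    for s, e, _ in segs:
        length = e - s + 1
        if off < length:
            return s + off if gene.strand == "+" else e - off
        off -= length
    raise ValueError("offset beyond CDS")


def simulate_genome_annotation(
    config: SimConfig, truth: pd.DataFrame | None = None,
) -> tuple[list[GeneModel], dict[str, str], list[VariantRecord], pd.DataFrame]:
    """Synthetic chromosomes, gene models, and variants with planted impacts.

    Gene ids match the count matrix.  If ``truth`` is given, genes with a
    planted ASE direction in any tissue receive ``ase_variant_multiplier``
    times the background variant rate — the variant-density enrichment the
    analysis is meant to detect.  Returns (gene models, genome, variants,
    variant truth table).
    """
    rng = config.rng(3)
    G = config.n_genes
    gene_ids = [f"gene{g:05d}" for g in range(1, G + 1)]
    ase_genes: set[str] = set()
    if truth is not None:
        sub = truth[truth["ase_direction"] != "none"]
        ase_genes = set(sub["gene_id"])

    cds_seq = _transcript_cds()
    utr5 = "".join(rng.choice(list("ACGT"), _UTR5))
    utr3 = "".join(rng.choice(list("ACGT"), _UTR3))
    intron = "GT" + "".join(rng.choice(list("ACGT"), _INTRON - 4)) + "AG"
    segment_plus = utr5 + cds_seq[:_CDS1] + intron + cds_seq[_CDS1:] + utr3

    genes: list[GeneModel] = []
    genome: dict[str, str] = {}
    pitch = _GENE_LEN + config.intergenic_gap
    strands = rng.choice(["+", "-"], size=G)
    n_chrom = (G + config.genes_per_chrom - 1) // config.genes_per_chrom
    for c in range(n_chrom):
        lo, hi = c * config.genes_per_chrom, min((c + 1) * config.genes_per_chrom, G)
        n_here = hi - lo
        length = config.intergenic_gap + n_here * pitch
        chrom = f"chrSim{c + 1}"
        seq = list("".join(rng.choice(list("ACGT"), length)))
        for i in range(n_here):
            g0 = config.intergenic_gap + i * pitch + 1  # 1-based segment start
            strand = strands[lo + i]
            block = segment_plus if strand == "+" else _revcomp(segment_plus)
            seq[g0 - 1: g0 - 1 + _GENE_LEN] = list(block)
            exons, cds = _gene_layout(g0, strand)
            genes.append(GeneModel(gene_id=gene_ids[lo + i], chrom=chrom,
                                   strand=strand, exons=exons, cds=cds))
        genome[chrom] = "".join(seq)

    # codon indices usable for planting (skip start and stop codons)
    tgg = [i for i in range(1, _N_CODONS - 1) if cds_seq[3 * i: 3 * i + 3] == "TGG"]
    ctg = [i for i in range(1, _N_CODONS - 1) if cds_seq[3 * i: 3 * i + 3] == "CTG"]
    gga = [i for i in range(1, _N_CODONS - 1) if cds_seq[3 * i: 3 * i + 3] == "GGA"]

    passing_info = {"QD": 20.0, "SOR": 1.0, "FS": 5.0, "MQ": 60.0,
                    "MQRankSum": 0.0, "ReadPosRankSum": 0.0}

    def plant(gene: GeneModel, impact: str, used: set[int], vid: str,
              chrom_seq: str) -> VariantRecord | None:
        def snp_at(codon_idx: int, within: int, ref_t: str, alt_t: str) -> VariantRecord:
            off = codon_idx * 3 + within
            pos = _genomic_pos_of_cds_offset(gene, off)
            ref, alt = (ref_t, alt_t) if gene.strand == "+" else (
                ref_t.translate(_COMP), alt_t.translate(_COMP))
            return VariantRecord(chrom=gene.chrom, pos=pos, ref=ref, alt=alt,
                                 variant_id=vid, qual=100.0, info=dict(passing_info))

        if impact == "HIGH":
            if rng.random() < 0.5:
                free = [i for i in tgg if i not in used]
                if free:
                    i = int(rng.choice(free))
                    used.add(i)
                    return snp_at(i, 2, "G", "A")  # TGG -> TGA, stop gained
            free = [i for i in ctg if i not in used]
            if not free:
                return None
            i = int(rng.choice(free))
            used.add(i)
            # 2-bp deletion anchored at the codon start: frameshift
            pos = _genomic_pos_of_cds_offset(gene, i * 3)
            if gene.strand == "-":
                pos -= 2
            ref = chrom_seq[pos - 1: pos + 2]
            return VariantRecord(chrom=gene.chrom, pos=pos, ref=ref, alt=ref[0],
                                 variant_id=vid, qual=100.0, info=dict(passing_info))
        if impact == "MODERATE":
            free = [i for i in ctg if i not in used]
            if not free:
                return None
            i = int(rng.choice(free))
            used.add(i)
            return snp_at(i, 0, "C", "A")  # CTG(Leu) -> ATG(Met), missense
        if impact == "LOW":
            free = [i for i in gga if i not in used]
            if not free:
                return None
            i = int(rng.choice(free))
            used.add(i)
            return snp_at(i, 2, "A", "G")  # GGA -> GGG, synonymous
        raise AssertionError(impact)

    variants: list[VariantRecord] = []
    truth_rows: list[tuple[str, str]] = []
    impact_names = list(IMPACTS)
    impact_p = [config.impact_category_probs[k] for k in impact_names]
    vid_n = 0
    for gene in genes:
        rate = config.n_variants_per_gene
        if gene.gene_id in ase_genes:
            rate *= config.ase_variant_multiplier
        k = rng.poisson(rate)
        used: set[int] = set()
        chrom_seq = genome[gene.chrom]
        for _ in range(k):
            impact = impact_names[rng.choice(len(impact_names), p=impact_p)]
            vid_n += 1
            vid = f"var{vid_n:06d}"
            if impact == "MODIFIER":
                # intronic SNP (clear of the 2-bp splice sites), so the
                # variant stays attributed to its source gene
                s, e = gene.introns()[0]
                pos = int(rng.integers(s + 3, e - 2))
                ref = chrom_seq[pos - 1]
                alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref]
                rec = VariantRecord(chrom=gene.chrom, pos=pos, ref=ref, alt=alt,
                                    variant_id=vid, qual=100.0,
                                    info=dict(passing_info))
            else:
                rec = plant(gene, impact, used, vid, chrom_seq)
                if rec is None:
                    vid_n -= 1
                    continue
            variants.append(rec)
            truth_rows.append((rec.variant_id, impact))
    var_truth = pd.DataFrame(truth_rows, columns=["variant_id", "impact"])
    return genes, genome, variants, var_truth


def simulate_term_map(config: SimConfig, truth: pd.DataFrame) -> pd.DataFrame:
    """Random gene-term annotations plus one term enriched in planted DEGs."""
    rng = config.rng(4)
    gene_ids = sorted(truth["gene_id"].unique())
    de_genes = sorted(set(truth.loc[truth["de_status"], "gene_id"]))
    rows = []
    for t in range(1, config.n_terms + 1):
        size = max(2, rng.poisson(config.term_size_mean))
        size = min(size, len(gene_ids))
        members = rng.choice(gene_ids, size=size, replace=False)
        rows += [(f"TERM{t:04d}", g) for g in sorted(members)]
    if de_genes:
        size = min(max(2, int(config.term_size_mean)), len(de_genes))
        members = rng.choice(de_genes, size=size, replace=False)
        rows += [("TERM_DE_ENRICHED", g) for g in sorted(members)]
    return pd.DataFrame(rows, columns=["term_id", "gene_id"])


def write_fixture_set(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every synthetic input and write it under ``outdir``.

    Byte-identical for identical configs.  Returns the path of each file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm, truth = simulate_trio_counts(config)
    allelic = simulate_allelic_counts(config, truth)
    genes, genome, variants, var_truth = simulate_genome_annotation(config, truth)
    terms = simulate_term_map(config, truth)

    paths = {
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "allelic": outdir / "allelic_counts.tsv",
        "gff": outdir / "genes.gff3",
        "vcf": outdir / "variants.vcf",
        "fasta": outdir / "genome.fa",
        "terms": outdir / "term_map.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_variants": outdir / "truth_variants.tsv",
    }
    hio.write_counts(cm, paths["counts"], paths["samples"])
    hio.write_table(allelic, paths["allelic"])
    hio.write_gff(genes, paths["gff"])
    hio.write_variants(variants, paths["vcf"],
                       contigs={c: len(s) for c, s in genome.items()})
    hio.write_fasta(genome, paths["fasta"])
    hio.write_table(terms, paths["terms"])
    hio.write_table(truth, paths["truth_genes"])
    hio.write_table(var_truth, paths["truth_variants"])
    return paths
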