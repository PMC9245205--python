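"""Readers, writers and validated in-memory containers.

All external formats the pipeline touches live here: the counts TSV +
sample sheet, a GFF3 subset (gene/mRNA/exon/CDS with phase), a VCF v4.2
subset with the hard-filter INFO metrics, FASTA, allelic-count and truth
tables.  Coordinates are 1-based inclusive everywhere (VCF and GFF3
convention); no half-open arithmetic leaks out of this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ROLES = ("maternal", "paternal", "hybrid")

#: INFO keys carried for hard-filter testing, in written order.
INFO_KEYS = ("QD", "SOR", "FS", "MQ", "MQRankSum", "ReadPosRankSum")


class SchemaError(ValueError):
    """An input file violates the declared schema."""


# ---------------------------------------------------------------------------
# counts + sample sheet
# ---------------------------------------------------------------------------


@dataclass
class CountsMatrix:
    """Gene x sample raw read counts with aligned sample metadata.

    ``counts`` is indexed by gene_id with one integer column per sample;
    ``samples`` is indexed by sample_id with columns
    (accession, role, tissue, replicate).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            # allow any order in the sheet but require the same set
            missing = set(self.counts.columns) ^ set(self.samples.index)
            if missing:
                raise SchemaError(f"counts/sheet sample mismatch: {sorted(missing)}")
            self.samples = self.samples.loc[list(self.counts.columns)]
        bad_role = set(self.samples["role"]) - set(ROLES)
        if bad_role:
            raise SchemaError(f"unknown roles {sorted(bad_role)}; expected {ROLES}")

    def sample_ids(self, role: str | None = None, tissue: str | None = None,
                   accession: str | None = None) -> list[str]:
        m = pd.Series(True, index=self.samples.index)
        if role is not None:
            m &= self.samples["role"] == role
        if tissue is not None:
            m &= self.samples["tissue"] == tissue
        if accession is not None:
            m &= self.samples["accession"] == accession
        return list(self.samples.index[m])

    @property
    def tissues(self) -> list[str]:
        return sorted(self.samples["tissue"].unique())


def read_counts(counts_path: str | Path, sheet_path: str | Path) -> CountsMatrix:
    """Load a counts TSV plus its sample sheet, strictly validated.

    Counts must be non-negative integers (the NB model needs them);
    fractional upstream estimates are rejected, not rounded.
    """
    raw = pd.read_csv(counts_path, sep="\t", dtype={0: str})
    if raw.columns[0] != "gene_id":
        raise SchemaError("first counts column must be 'gene_id'")
    if raw["gene_id"].duplicated().any():
        dups = raw.loc[raw["gene_id"].duplicated(), "gene_id"].tolist()
        raise SchemaError(f"duplicated gene_id: {dups[:5]}")
    counts = raw.set_index("gene_id")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise SchemaError("non-numeric count entries")
    if (arr < 0).any():
        raise SchemaError("negative count entries")
    if not np.allclose(arr, np.round(arr)):
        raise SchemaError("non-integer count entries")
    counts = counts.astype(np.int64)

    sheet = pd.read_csv(sheet_path, sep="\t", dtype=str)
    required = {"sample_id", "accession", "role", "tissue", "replicate"}
    if not required <= set(sheet.columns):
        raise SchemaError(f"sample sheet must have columns {sorted(required)}")
    sheet = sheet.set_index("sample_id")
    sheet["replicate"] = sheet["replicate"].astype(int)
    extra = set(sheet.index) - set(counts.columns)
    if extra:
        raise SchemaError(f"sheet samples absent from counts header: {sorted(extra)}")
    missing = set(counts.columns) - set(sheet.index)
    if missing:
        raise SchemaError(f"counts samples absent from sheet: {sorted(missing)}")
    return CountsMatrix(counts=counts, samples=sheet)


def write_counts(cm: CountsMatrix, counts_path: str | Path, sheet_path: str | Path) -> None:
    cm.counts.reset_index().to_csv(counts_path, sep="\t", index=False)
    cm.samples.reset_index().to_csv(sheet_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene models (GFF3 subset)
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """One gene with a single transcript: exons plus CDS with phase.

    Intervals are 1-based inclusive (start, end) tuples sorted by start;
    ``cds`` tuples carry phase as a third element.  ``valid_cds`` is
    False when the CDS length (after phase adjustment) is not a multiple
    of three; such genes are excluded from coding-effect calls.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int, int]] = field(default_factory=list)
    valid_cds: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise SchemaError(f"{self.gene_id}: strand must be + or -")
        if sorted(self.exons) != self.exons:
            warnings.warn(f"{self.gene_id}: unsorted exons, sorting", stacklevel=2)
            self.exons = sorted(self.exons)
        if sorted(self.cds) != self.cds:
            warnings.warn(f"{self.gene_id}: unsorted CDS, sorting", stacklevel=2)
            self.cds = sorted(self.cds)
        for ivs in (self.exons, [c[:2] for c in self.cds]):
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise SchemaError(f"{self.gene_id}: overlapping intervals")
        for s, e, _ in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise SchemaError(f"{self.gene_id}: CDS not contained in exons")
        if self.cds:
            total = sum(e - s + 1 for s, e, _ in self.cds) - self.first_phase
            if total % 3 != 0:
                warnings.warn(
                    f"{self.gene_id}: CDS length not divisible by 3; "
                    "excluded from coding-effect calls",
                    stacklevel=2,
                )
                self.valid_cds = False

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    @property
    def first_phase(self) -> int:
        """Phase of the transcript-first CDS segment (strand-aware)."""
        if not self.cds:
            return 0
        seg = self.cds[0] if self.strand == "+" else self.cds[-1]
        return seg[2]

    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1 + 1, s2 - 1)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
            if s2 - e1 > 1
        ]


_GFF_COLS = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]


def _attr(attrs: str, key: str) -> str | None:
    for part in attrs.rstrip(";").split(";"):
        k, _, v = part.partition("=")
        if k.strip() == key:
            return v
    return None


def read_gff(path: str | Path) -> list[GeneModel]:
    """Parse the GFF3 subset into GeneModel objects (one transcript per gene)."""
    df = pd.read_csv(path, sep="\t", comment="#", names=_GFF_COLS,
                     dtype={"start": int, "end": int})
    genes: dict[str, dict] = {}
    mrna_to_gene: dict[str, str] = {}
    for row in df.itertuples(index=False):
        if row.type == "gene":
            gid = _attr(row.attributes, "ID")
            genes[gid] = {"chrom": row.seqid, "strand": row.strand, "exons": [], "cds": []}
        elif row.type == "mRNA":
            mrna_to_gene[_attr(row.attributes, "ID")] = _attr(row.attributes, "Parent")
    for row in df.itertuples(index=False):
        if row.type in ("exon", "CDS"):
            parent = _attr(row.attributes, "Parent")
            gid = mrna_to_gene.get(parent, parent)
            if gid not in genes:
                raise SchemaError(f"feature parent {parent!r} has no gene record")
            if row.type == "exon":
                genes[gid]["exons"].append((row.start, row.end))
            else:
                phase = 0 if row.phase in (".", None) else int(row.phase)
                genes[gid]["cds"].append((row.start, row.end, phase))
    out = []
    for gid, d in genes.items():
        out.append(GeneModel(gene_id=gid, chrom=d["chrom"], strand=d["strand"],
                             exons=sorted(d["exons"]), cds=sorted(d["cds"])))
    return out


def write_gff(genes: Sequence[GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        tid = f"{g.gene_id}.t1"
        lines.append("\t".join([g.chrom, "heteroseq", "gene", str(g.start), str(g.end),
                                ".", g.strand, ".", f"ID={g.gene_id}"]))
        lines.append("\t".join([g.chrom, "heteroseq", "mRNA", str(g.start), str(g.end),
                                ".", g.strand, ".", f"ID={tid};Parent={g.gene_id}"]))
        for s, e in g.exons:
            lines.append("\t".join([g.chrom, "heteroseq", "exon", str(s), str(e),
                                    ".", g.strand, ".", f"Parent={tid}"]))
        for s, e, ph in g.cds:
            lines.append("\t".join([g.chrom, "heteroseq", "CDS", str(s), str(e),
                                    ".", g.strand, str(ph), f"Parent={tid}"]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# variants (VCF v4.2 subset)
# ---------------------------------------------------------------------------


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    variant_id: str = "."
    qual: float | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise SchemaError(f"{self.variant_id}: pos must be >= 1")
        if not self.ref or not self.alt or self.ref == self.alt:
            raise SchemaError(f"{self.variant_id}: ref/alt must be non-empty and differ")

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def end(self) -> int:
        """Last reference base touched (== pos for SNPs and insertions)."""
        return self.pos + len(self.ref) - 1


def read_variants(path: str | Path) -> list[VariantRecord]:
    """Read a VCF; multi-allelic lines are split into one record per ALT."""
    import pysam

    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = {}
            for key in INFO_KEYS:
                if key in rec.info:
                    val = rec.info[key]
                    info[key] = float(val[0] if isinstance(val, tuple) else val)
            for alt in rec.alts or ():
                out.append(VariantRecord(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                    variant_id=rec.id or ".",
                    qual=None if rec.qual is None else float(rec.qual),
                    info=dict(info)))
    return out


def write_variants(records: Sequence[VariantRecord], path: str | Path,
                   contigs: Mapping[str, int] | None = None) -> None:
    """Write a minimal VCF v4.2 with the filter-metric INFO declarations."""
    header = ["##fileformat=VCFv4.2"]
    if contigs is None:
        contigs = {}
        for r in records:
            contigs[r.chrom] = max(contigs.get(r.chrom, 0), r.end + 1000)
    for name, length in contigs.items():
        header.append(f"##contig=<ID={name},length={length}>")
    for key in INFO_KEYS:
        header.append(f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">')
    header.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    lines = header
    for r in sorted(records, key=lambda v: (v.chrom, v.pos, v.alt)):
        info = ";".join(f"{k}={r.info[k]:g}" for k in INFO_KEYS if k in r.info) or "."
        qual = "." if r.qual is None else f"{r.qual:g}"
        lines.append("\t".join([r.chrom, str(r.pos), r.variant_id, r.ref, r.alt,
                                qual, ".", info]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# simple TSV tables
# ---------------------------------------------------------------------------

ALLELIC_COLS = ["gene_id", "tissue", "replicate", "maternal_count", "paternal_count"]


def read_allelic_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(ALLELIC_COLS) - set(df.columns)
    if missing:
        raise SchemaError(f"allelic counts missing columns {sorted(missing)}")
    if (df[["maternal_count", "paternal_count"]] < 0).any().any():
        raise SchemaError("negative allelic counts")
    return df[ALLELIC_COLS]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_term_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"term_id", "gene_id"} <= set(df.columns):
        raise SchemaError("term map needs columns term_id, gene_id")
    return df[["term_id", "gene_id"]]
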