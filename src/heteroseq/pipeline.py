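"""End-to-end orchestration of the heterosis analysis.

Stages (dependency order): simulate -> de -> dominance -> ase ->
patterns -> overlap -> enrich -> varannot.  Each stage writes TSV
outputs under the configured output directory; a MANIFEST file lists
completed stages so partial runs are recognisable, and run_report.json
records versions, seed, stage tallies and wall time.  Identical
configuration (including seed) produces byte-identical outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, ase, diffexpr, dominance, geneset, simdata, varannot
from . import io as hio

STAGES = ("simulate", "de", "dominance", "ase", "patterns", "overlap",
          "enrich", "varannot")

# fixed RNG stream ids per stage, so toggling one stage never perturbs another
_STREAM = {"overlap": 10, "varannot": 11}


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    simulate: dict | None = None          # SimConfig overrides; None = use inputs
    inputs: dict = field(default_factory=dict)
    deg_fdr: float = 0.01
    deg_lfc: float = 1.0
    ase_padj: float = 0.05
    active_min_reads: int = 2
    active_min_reps: int = 2
    ase_min_depth: int = 10
    n_sim: int = 1000
    dghp_union: bool = True
    pseudocount_reporting: bool = False
    rank_sum_sign_fix: bool = True

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        for name in ("deg_fdr", "deg_lfc", "ase_padj"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.simulate is None:
            required = ["counts", "samples"]
            missing = [k for k in required if k not in self.inputs]
            if missing:
                raise ValueError(f"config must either enable 'simulate' or "
                                 f"provide inputs: missing {missing}")
            for key, p in self.inputs.items():
                if not Path(p).exists():
                    raise ValueError(f"input path for {key!r} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thresholds = raw.pop("thresholds", {})
        flags = raw.pop("flags", {})
        return cls(**{**raw, **thresholds, **flags})


def _contrasts(cm: hio.CountsMatrix, tissue: str) -> dict[str, tuple[list, list]]:
    m = cm.sample_ids(role="maternal", tissue=tissue)
    p = cm.sample_ids(role="paternal", tissue=tissue)
    h = cm.sample_ids(role="hybrid", tissue=tissue)
    return {"hybrid_vs_mother": (m, h), "hybrid_vs_father": (p, h),
            "mother_vs_father": (p, m)}


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages; returns the run report dict."""
    t0 = time.time()
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    report: dict = {"package": "heteroseq", "version": __version__,
                    "seed": config.seed, "stages": {}}
    manifest_path = out / "MANIFEST"
    try:
        _run(config, stages, out, manifest, report)
        report["complete"] = True
    except Exception:
        report["complete"] = False
        manifest.append("INCOMPLETE")
        raise
    finally:
        report["wall_time_s"] = round(time.time() - t0, 3)
        manifest_path.write_text("\n".join(manifest) + "\n")
        (out / "run_report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report


def _run(config: PipelineConfig, stages, out: Path, manifest: list, report: dict) -> None:
    paths = dict(config.inputs)

    if "simulate" in stages and config.simulate is not None:
        sim_cfg = simdata.SimConfig(seed=config.seed, **config.simulate)
        sim_paths = simdata.write_fixture_set(sim_cfg, out / "sim")
        paths = {k: str(v) for k, v in sim_paths.items()}
        report["stages"]["simulate"] = {"n_genes": sim_cfg.n_genes,
                                        "tissues": list(sim_cfg.tissues)}
        manifest.append("simulate")

    cm = hio.read_counts(paths["counts"], paths["samples"])
    sf = diffexpr.size_factors(cm)
    tissues = cm.tissues

    de_results: dict[tuple[str, str], pd.DataFrame] = {}
    if "de" in stages:
        active: dict[str, set] = {}
        for tissue in tissues:
            for acc in sorted(cm.samples["accession"].unique()):
                grp = cm.sample_ids(accession=acc, tissue=tissue)
                if len(grp) >= 2:
                    active[f"{acc}_{tissue}"] = diffexpr.call_active_genes(
                        cm, grp, config.active_min_reads, config.active_min_reps)
        pd.DataFrame([(k, len(v)) for k, v in active.items()],
                     columns=["group", "n_active"]).to_csv(
            out / "active_genes.tsv", sep="\t", index=False)
        corr = diffexpr.sample_correlation(cm, sf)
        corr.to_csv(out / "sample_correlation_r2.tsv", sep="\t")
        for tissue in tissues:
            for name, (ga, gb) in _contrasts(cm, tissue).items():
                res = diffexpr.nb_wald_test(cm, ga, gb, sf=sf,
                                            fdr_threshold=config.deg_fdr,
                                            lfc_threshold=config.deg_lfc)
                de_results[(tissue, name)] = res
                hio.write_table(res, out / f"de_{tissue}_{name}.tsv")
        report["stages"]["de"] = {
            f"{t}_{n}": int(r["is_deg"].sum()) for (t, n), r in de_results.items()}
        manifest.append("de")

    dghp: dict[str, set] = {}
    if "dominance" in stages:
        mode = "union" if config.dghp_union else "intersection"
        summary = {}
        for tissue in tissues:
            table, pct = dominance.classify_dghp(
                cm, de_results[(tissue, "hybrid_vs_mother")],
                de_results[(tissue, "hybrid_vs_father")], tissue,
                size_factors=sf, mode=mode)
            dghp[tissue] = set(table["gene_id"])
            hio.write_table(table, out / f"dominance_{tissue}.tsv")
            pct.rename_axis("category").reset_index().to_csv(
                out / f"dominance_{tissue}_percent.tsv", sep="\t", index=False)
            summary[tissue] = {c: round(float(pct[c]), 2) for c in pct.index}
        report["stages"]["dominance"] = summary
        manifest.append("dominance")

    ase_results: dict[str, pd.DataFrame] = {}
    if "ase" in stages and "allelic" in paths:
        allelic = hio.read_allelic_counts(paths["allelic"])
        for tissue in tissues:
            res = ase.ase_test(allelic, tissue, min_depth=config.ase_min_depth,
                               padj_threshold=config.ase_padj)
            ase_results[tissue] = res
            hio.write_table(res, out / f"ase_{tissue}.tsv")
        report["stages"]["ase"] = {
            t: int(r["is_aseg"].sum()) for t, r in ase_results.items()}
        manifest.append("ase")

    if "patterns" in stages and len(ase_results) >= 2:
        t1, t2 = tissues[:2]
        table, counts = ase.classify_aseg_patterns(ase_results[t1], ase_results[t2])
        hio.write_table(table, out / "aseg_patterns.tsv")
        counts.rename_axis("pattern").reset_index().to_csv(
            out / "aseg_pattern_counts.tsv", sep="\t", index=False)
        report["stages"]["patterns"] = {k: int(v) for k, v in counts.items()}
        manifest.append("patterns")

    aseg_union: set[str] = set()
    for res in ase_results.values():
        aseg_union |= set(res.loc[res["is_aseg"], "gene_id"])

    if "overlap" in stages and ase_results and de_results:
        rows = []
        for tissue in tissues:
            parental = set(de_results[(tissue, "mother_vs_father")]
                           .query("is_deg")["gene_id"])
            asegs = set(ase_results[tissue].query("is_aseg")["gene_id"])
            universe = sorted(cm.counts.index)
            rng = np.random.default_rng([config.seed, _STREAM["overlap"]])
            r = geneset.overlap_resampling_test(parental, asegs, universe,
                                                n_sim=config.n_sim, rng=rng)
            frac = len(parental & asegs) / len(asegs) * 100 if asegs else np.nan
            rows.append((tissue, len(parental), len(asegs), r.observed_overlap,
                         frac, r.null_mean, r.null_sd, r.t_stat, r.p_t,
                         r.p_empirical))
        df = pd.DataFrame(rows, columns=[
            "tissue", "n_parental_degs", "n_asegs", "observed_overlap",
            "pct_asegs_parentally_de", "null_mean", "null_sd", "t_stat",
            "p_t", "p_empirical"])
        hio.write_table(df, out / "overlap_parental_de_vs_aseg.tsv")
        report["stages"]["overlap"] = df.set_index("tissue")["p_empirical"].to_dict()
        manifest.append("overlap")

    if "enrich" in stages and "terms" in paths and dghp:
        term_map = hio.read_term_map(paths["terms"])
        universe = sorted(cm.counts.index)
        for tissue in tissues:
            if not dghp.get(tissue):
                continue
            enr = geneset.hypergeom_enrichment(dghp[tissue], term_map, universe)
            hio.write_table(enr, out / f"enrichment_dghp_{tissue}.tsv")
        report["stages"]["enrich"] = {"n_terms": int(term_map["term_id"].nunique())}
        manifest.append("enrich")

    if "varannot" in stages and all(k in paths for k in ("vcf", "gff", "fasta")):
        records = hio.read_variants(paths["vcf"])
        verdicts = varannot.filter_variants(
            records, rank_sum_sign_fix=config.rank_sum_sign_fix)
        passing = [v.variant for v in verdicts if v.passed]
        genes = hio.read_gff(paths["gff"])
        genome = hio.read_fasta(paths["fasta"])
        effects = varannot.classify_variants(passing, genes, genome)
        eff_df = varannot.effects_to_frame(effects)
        hio.write_table(eff_df, out / "variant_effects.tsv")
        varannot.effects_by_gene(effects).reset_index().to_csv(
            out / "variant_counts_by_gene.tsv", sep="\t", index=False)
        report["stages"]["varannot"] = {
            "n_records": len(records), "n_pass": len(passing),
            "impacts": eff_df["impact"].value_counts().to_dict()}
        if aseg_union:
            rng = np.random.default_rng([config.seed, _STREAM["varannot"]])
            dens = geneset.variant_density_comparison(
                eff_df, aseg_union, sorted(cm.counts.index),
                n_sim=config.n_sim, rng=rng)
            hio.write_table(dens, out / "variant_density_asegs.tsv")
        manifest.append("varannot")
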