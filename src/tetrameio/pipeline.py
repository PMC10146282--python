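"""End-to-end pipeline: simulate -> mine -> dose -> infer -> meiosis ->
map -> marey -> pcoa -> assoc -> genes.

Stages exchange plain-text TSV/CSV through a run directory, so any stage
can be re-run from cached upstream outputs and a run is fully described by
the resolved config written next to the outputs.  All randomness flows
from ``config.seed``; the only stochastic stage is ``simulate``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc_mod
from . import dosing, dsnp, gametes, mapping, meiosis, synthdata
from .config import PipelineConfig
from .io import read_matrix, write_matrix

log = logging.getLogger("tetrameio")

STAGES = ["simulate", "mine", "dose", "infer", "meiosis", "map", "marey",
          "pcoa", "assoc", "genes"]

PARENTS = {"ovule": synthdata.MEDICA, "pollen": synthdata.TRIFOLIATA}


def _genome(config: PipelineConfig) -> synthdata.GenomeSpec:
    return synthdata.default_genome(
        config.n_chromosomes, config.chrom_length,
        config.map_length_morgans, config.centromere_frac)


# ---------------------------------------------------------------------------
# truth serialization
# ---------------------------------------------------------------------------

def gametes_to_table(gams: list[synthdata.GameteTruth]) -> pd.DataFrame:
    rows = []
    for g in gams:
        for chrom, (c1, c2) in g.chromatids.items():
            for ci, track in enumerate((c1, c2), start=1):
                prev = 0.0
                for end, anc in track:
                    rows.append((g.gamete_id, chrom, ci, prev, end, anc,
                                 g.pairing[chrom]))
                    prev = end
    return pd.DataFrame(rows, columns=["gamete_id", "chrom", "chromatid",
                                       "start", "end", "ancestor", "pairing"])


def gametes_from_table(table: pd.DataFrame) -> list[synthdata.GameteTruth]:
    gams = []
    for gid, grp in table.groupby("gamete_id", sort=False):
        chromatids: dict[str, tuple] = {}
        pairing: dict[str, str] = {}
        for chrom, cgrp in grp.groupby("chrom", sort=False):
            tracks = []
            for ci in (1, 2):
                seg = cgrp[cgrp["chromatid"] == ci].sort_values("start")
                tracks.append([(float(e), a) for e, a in
                               zip(seg["end"], seg["ancestor"])])
            chromatids[chrom] = (tracks[0], tracks[1])
            pairing[chrom] = cgrp["pairing"].iloc[0]
        gams.append(synthdata.GameteTruth(gid, chromatids, pairing, {}))
    return gams


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    rng = np.random.default_rng(config.seed)
    genome = _genome(config)
    chroms = genome.names
    genome.centromere_table().to_csv(outdir / "centromeres.tsv", sep="\t",
                                     index=False)

    panel = synthdata.synthetic_dsnp_panel(
        genome, config.dsnps_per_taxon_per_chrom, rng)
    panel.to_csv(outdir / "panel_truth.tsv", sep="\t", index=False)

    geno, taxon_map = synthdata.synthetic_reference_genotypes(
        panel, config.ref_accessions_per_taxon, config.ref_missing_rate, rng)
    geno.to_csv(outdir / "ref_genotypes.tsv", sep="\t", na_rep="NA")
    taxon_map.to_csv(outdir / "taxon_map.tsv", sep="\t")

    volk, citru = synthdata.build_parent_karyotypes(genome)
    ovules = synthdata.simulate_meiosis(
        volk, genome, synthdata.MeiosisParams(config.tau_ovule(chroms)),
        config.n_hybrids, rng, id_prefix="ov")
    pollens = synthdata.simulate_meiosis(
        citru, genome, synthdata.MeiosisParams(config.tau_pollen(chroms)),
        config.n_hybrids, rng, id_prefix="po")
    hybrids = synthdata.form_hybrids(ovules, pollens)

    for name, gams in (("ovule", ovules), ("pollen", pollens)):
        gametes_to_table(gams).to_csv(outdir / f"truth_{name}.tsv",
                                      sep="\t", index=False)
    pd.DataFrame({"hybrid_id": [h.hybrid_id for h in hybrids],
                  "ovule_id": [h.ovule.gamete_id for h in hybrids],
                  "pollen_id": [h.pollen.gamete_id for h in hybrids],
                  }).to_csv(outdir / "hybrids.tsv", sep="\t", index=False)

    model = synthdata.ReadCountModel(config.depth, config.eps,
                                     config.missing_rate)
    counts = synthdata.simulate_read_counts(hybrids, panel, model, rng)
    counts.to_csv(outdir / "read_counts.tsv", sep="\t", index=False)

    # phenotypes from gamete doses at the configured QTL positions
    qtl_cols = {}
    effects = []
    for i, q in enumerate(config.qtls):
        parent = q["parent"]
        pos = np.array([q["pos_frac"] * genome.length_of(q["chrom"])])
        ancestor = PARENTS[parent]
        source = {"ovule": [h.ovule for h in hybrids],
                  "pollen": [h.pollen for h in hybrids]}[parent]
        qid = f"qtl{i}_{parent}_{q['chrom']}"
        qtl_cols[qid] = [int(g.ancestor_dose(q["chrom"], pos, ancestor)[0])
                         for g in source]
        effects.append((qid, float(q["beta"])))
    qtl_doses = pd.DataFrame(qtl_cols,
                             index=[h.hybrid_id for h in hybrids])
    pheno = synthdata.simulate_phenotypes(
        qtl_doses, effects, config.noise_sd, config.phenotype_intercept,
        rng, trait=config.trait_name)
    pheno.to_csv(outdir / "phenotypes.csv", index_label="id")

    genes = pd.DataFrame([
        {"gene": g["gene"], "trait": g["trait"], "chrom": g["chrom"],
         "start": int(g["start_frac"] * genome.length_of(g["chrom"])),
         "end": int(g["start_frac"] * genome.length_of(g["chrom"])
                    + g["width"])}
        for g in config.genes])
    genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)


def _stage_mine(config: PipelineConfig, outdir: Path) -> None:
    geno = pd.read_csv(outdir / "ref_genotypes.tsv", sep="\t",
                       index_col=["chrom", "pos"], na_values="NA")
    taxon_map = pd.read_csv(outdir / "taxon_map.tsv", sep="\t",
                            index_col=0)["taxon"]
    panel = dsnp.mine_dsnps(geno, taxon_map, config.max_missing_dsnp)
    panel.to_csv(outdir / "panel_mined.tsv", sep="\t", index=False)
    dsnp.panel_summary(panel).to_csv(outdir / "dsnp_summary.tsv", sep="\t")
    log.info("mined %d DSNPs", len(panel))


def _stage_dose(config: PipelineConfig, outdir: Path) -> None:
    panel = pd.read_csv(outdir / "panel_mined.tsv", sep="\t")
    counts = pd.read_csv(outdir / "read_counts.tsv", sep="\t")
    pw = dosing.window_partition(panel, config.window_size)
    pw.to_csv(outdir / "panel_windows.tsv", sep="\t", index=False)
    dosing.window_table(pw).to_csv(outdir / "windows.tsv", sep="\t",
                                   index=False)
    for parent, ancestor in PARENTS.items():
        mat = dosing.call_hybrid_doses(
            counts, pw, ancestor, ploidy=4, eps=config.eps,
            min_reads=config.min_reads, lr_threshold=config.lr_threshold)
        write_matrix(mat, outdir / f"hybrid_dose_{ancestor}.tsv")


def _stage_infer(config: PipelineConfig, outdir: Path) -> None:
    windows = pd.read_csv(outdir / "windows.tsv", sep="\t")
    report: dict = {}
    for parent, ancestor in PARENTS.items():
        hyb = read_matrix(outdir / f"hybrid_dose_{ancestor}.tsv")
        gam, n_bad = gametes.infer_gametes(hyb)
        gam, n_single = gametes.remove_singletons(gam, windows)
        gam, filt = gametes.filter_matrix(
            gam, config.max_window_missing, config.max_individual_missing)
        gam, aberr = gametes.drop_aberrant_individuals(
            gam, windows, config.aberrant_k_iqr)
        write_matrix(gam, outdir / f"gamete_{parent}.tsv")
        report[parent] = {
            "ancestor": ancestor,
            "inconsistent_doses": n_bad,
            "singletons_removed": n_single,
            "windows_dropped": filt["windows_dropped"],
            "individuals_dropped": filt["individuals_dropped"],
            "aberrant_dropped": [str(i) for i in
                                 aberr.index[aberr["dropped"]]],
            "final_shape": list(gam.shape),
        }
    (outdir / "cleaning_report.json").write_text(json.dumps(report, indent=2))


def _stage_meiosis(config: PipelineConfig, outdir: Path) -> None:
    windows = pd.read_csv(outdir / "windows.tsv", sep="\t")
    cen = pd.read_csv(outdir / "centromeres.tsv", sep="\t")
    for parent in PARENTS:
        gam = read_matrix(outdir / f"gamete_{parent}.tsv")
        meiosis.phr_by_window(gam).to_csv(
            outdir / f"phr_windows_{parent}.tsv", sep="\t",
            index_label="window_id")
        meiosis.phr_by_chromosome(gam, windows).to_csv(
            outdir / f"phr_chromosomes_{parent}.tsv", sep="\t",
            index_label="chrom")
        pp = meiosis.pp_per_chromosome(gam, windows, cen,
                                       step=config.tau_grid_step)
        pp.to_csv(outdir / f"pp_{parent}.tsv", sep="\t", index=False)
        scan = meiosis.tetrasomic_deviation_scan(
            gam, config.q_threshold, fdr_method=config.fdr_method)
        scan.to_csv(outdir / f"segregation_{parent}.tsv", sep="\t",
                    index=False)
        meiosis.deviation_summary(scan, windows).to_csv(
            outdir / f"segregation_summary_{parent}.tsv", sep="\t",
            index_label="chrom")


def _stage_map(config: PipelineConfig, outdir: Path) -> None:
    windows = pd.read_csv(outdir / "windows.tsv", sep="\t")
    for parent in PARENTS:
        gam = read_matrix(outdir / f"gamete_{parent}.tsv")
        rf = mapping.rf_matrix(gam, config.min_rf_overlap)
        groups = mapping.linkage_groups(rf, config.rf_threshold)
        groups.to_csv(outdir / f"linkage_groups_{parent}.tsv", sep="\t",
                      index_label="window_id")
        gmap = mapping.build_map(gam, windows, config.min_rf_overlap)
        gmap.to_csv(outdir / f"map_{parent}.tsv", sep="\t", index=False)
        mapping.map_summary(gmap).to_csv(
            outdir / f"map_summary_{parent}.tsv", sep="\t",
            index_label="chrom")


def _stage_marey(config: PipelineConfig, outdir: Path) -> None:
    for parent in PARENTS:
        gmap = pd.read_csv(outdir / f"map_{parent}.tsv", sep="\t")
        marey = mapping.marey_rate(gmap, config.loess_span,
                                   config.marey_min_markers)
        marey.to_csv(outdir / f"marey_{parent}.tsv", sep="\t", index=False)


def _stage_pcoa(config: PipelineConfig, outdir: Path) -> None:
    for parent in PARENTS:
        gam = read_matrix(outdir / f"gamete_{parent}.tsv")
        d = mapping.dissimilarity_matrix(gam)
        coords, pct = mapping.factorial_coordinates(d)
        coords.assign(**{"pct_" + c: pct[c] for c in pct.index}).to_csv(
            outdir / f"pcoa_{parent}.csv", index_label="id")


def _stage_assoc(config: PipelineConfig, outdir: Path) -> None:
    windows = pd.read_csv(outdir / "windows.tsv", sep="\t")
    pheno = pd.read_csv(outdir / "phenotypes.csv", index_col="id")
    for parent in PARENTS:
        gam = read_matrix(outdir / f"gamete_{parent}.tsv")
        res = assoc_mod.glm_scan(gam, pheno, windows, config.p_threshold)
        res.to_csv(outdir / f"association_{parent}.tsv", sep="\t",
                   index=False)


def _stage_genes(config: PipelineConfig, outdir: Path) -> None:
    windows = pd.read_csv(outdir / "windows.tsv", sep="\t")
    genes = pd.read_csv(outdir / "genes.tsv", sep="\t")
    hyb = read_matrix(outdir / f"hybrid_dose_{synthdata.TRIFOLIATA}.tsv")
    gam, _ = gametes.infer_gametes(hyb)
    table, frac = assoc_mod.gene_inheritance(gam, genes, windows)
    table.to_csv(outdir / "gene_inheritance.tsv", sep="\t", index=False)
    (outdir / "gene_inheritance_overall.json").write_text(json.dumps(
        {"frac_hybrids_at_least_one_dose_everywhere": frac}))


_STAGE_FUNCS = {
    "simulate": _stage_simulate, "mine": _stage_mine, "dose": _stage_dose,
    "infer": _stage_infer, "meiosis": _stage_meiosis, "map": _stage_map,
    "marey": _stage_marey, "pcoa": _stage_pcoa, "assoc": _stage_assoc,
    "genes": _stage_genes,
}


def _write_summary(outdir: Path) -> None:
    summary: dict = {}
    mined = pd.read_csv(outdir / "panel_mined.tsv", sep="\t")
    summary["n_dsnps"] = int(len(mined))
    for parent in PARENTS:
        s: dict = {}
        pp = pd.read_csv(outdir / f"pp_{parent}.tsv", sep="\t")
        s["mean_pp"] = float(pp.groupby("chrom")["chrom_pp"].first().mean())
        phr_c = pd.read_csv(outdir / f"phr_chromosomes_{parent}.tsv",
                            sep="\t", index_col="chrom")
        s["mean_phr"] = float(phr_c["phr"].mean())
        seg = pd.read_csv(outdir / f"segregation_summary_{parent}.tsv",
                          sep="\t", index_col="chrom")
        s["pct_windows_distorted"] = float(
            seg.loc["total", "pct_significant"])
        msum = pd.read_csv(outdir / f"map_summary_{parent}.tsv", sep="\t",
                           index_col="chrom")
        s["map_length_cm"] = float(msum.loc["total", "length_cm"])
        s["n_mapped_windows"] = int(msum.loc["total", "n_markers"])
        summary[parent] = s
    overall = json.loads((outdir / "gene_inheritance_overall.json")
                         .read_text())
    summary.update(overall)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 stages: list[str] | None = None) -> Path:
    """Run the requested stages (default: all) into ``outdir``; writes the
    resolved config next to the outputs and, after a full run, a summary
    JSON with the headline quantities."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    todo = STAGES if stages is None else stages
    bad = [s for s in todo if s not in _STAGE_FUNCS]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    config.to_yaml(outdir / "resolved_config.yaml")
    for stage in STAGES:
        if stage not in todo:
            continue
        log.info("stage %s", stage)
        try:
            _STAGE_FUNCS[stage](config, outdir)
        except Exception as exc:
            (outdir / "error.json").write_text(json.dumps(
                {"stage": stage, "error": str(exc)}))
            raise
    if set(STAGES) <= set(todo):
        _write_summary(outdir)
    return outdir
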