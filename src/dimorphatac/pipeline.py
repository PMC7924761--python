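"""Configuration-driven orchestration of the full analysis.

Stages run in the fixed order
simulate -> callpeaks -> consensus -> counts -> diff (stratified + pooled)
-> specificity -> annotate -> reldist -> motif -> coverage -> rnaseq,
each writing its TSV outputs before the next starts; a manifest with the
config hash, seed fan-out and per-stage row counts is written last, so a
failed stage leaves all prior outputs intact and identifiable.

Determinism: one global seed is fanned out to per-stage child seeds by
stable hashing of stage names, so a stage rerun in isolation reproduces
its in-pipeline output.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import coverage as cov
from . import diffacc, io, motif as motif_mod, rnaseq, simulate, specificity
from .peakcall import call_peaks, coverage_from_frame, peaks_to_frame

log = logging.getLogger("dimorphatac")

DEFAULT_THRESHOLDS = {"peak_q": 0.001, "da_fdr": 0.05, "motif_p": 1e-3}


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage child seed (< 2^31)."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def default_motif() -> motif_mod.PWM:
    """An 8-bp synthetic high-information motif used by the bundled demo
    (stands in for an in-vitro-selected binding preference)."""
    strong, weak = 0.91, 0.03
    cons = "TGCAACGT"
    probs = np.full((8, 4), weak)
    for i, b in enumerate(cons):
        probs[i, "ACGT".index(b)] = strong
    return motif_mod.PWM(motif_id="synthetic_fru_like", probs=probs)


class PipelineConfig:
    """Validated pipeline configuration (YAML-loadable)."""

    def __init__(self, seed: int = 0, outdir: str = "pipeline_out",
                 simulation: dict | None = None,
                 thresholds: dict | None = None,
                 consensus_min_samples: int = 2):
        self.seed = int(seed)
        self.outdir = Path(outdir)
        self.simulation = simulation or {}
        self.thresholds = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
        self.consensus_min_samples = consensus_min_samples
        for name, value in self.thresholds.items():
            if not (0 < value < 1):
                raise ValueError(f"threshold {name} must be in (0,1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "outdir": str(self.outdir),
            "simulation": self.simulation, "thresholds": self.thresholds,
            "consensus_min_samples": self.consensus_min_samples,
        }

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    t0 = time.time()
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.hash(), "seed": config.seed,
        "thresholds": config.thresholds, "stages": {},
    }

    def record(stage: str, **info):
        manifest["stages"][stage] = info
        log.info("stage %s: %s", stage, info)

    # --- simulate -----------------------------------------------------
    sim_kwargs = dict(config.simulation)
    sim_kwargs["seed"] = stage_seed(config.seed, "simulate")
    sim_config = simulate.SimulationConfig(**sim_kwargs)
    genome = sim_config.genome
    cm, truth = simulate.simulate_counts(sim_config)
    fragments = simulate.simulate_fragments(sim_config, cm)
    pwm = default_motif()
    records = simulate.simulate_sequences(sim_config, truth, pwm)
    genes = simulate.simulate_genes(sim_config)

    truth.peaks.to_csv(out / "truth_peaks.tsv", sep="\t", index=False)
    cm.to_frame().to_csv(out / "simulated_counts.tsv", sep="\t", index=False)
    truth.samples.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
    simulate.write_fragment_beds(fragments, out)
    simulate.write_fasta(records, out / "peak_sequences.fasta")
    io.write_gene_models(out / "genes.gtf", genes)
    io.write_intervals(out / "tether_sites.bed", truth.tether_sites, "BED3")
    record("simulate", peaks=len(truth.peaks), samples=len(truth.samples),
           fragments={s: len(df) for s, df in fragments.items()})

    # --- callpeaks ----------------------------------------------------
    peak_sets = []
    for sid, df in fragments.items():
        track = coverage_from_frame(df, genome, mode="midpoint")
        peaks = call_peaks(track, q_threshold=config.thresholds["peak_q"])
        peaks_to_frame(peaks).to_csv(out / f"peaks_{sid}.tsv", sep="\t",
                                     index=False)
        peak_sets.append(peaks)
    record("callpeaks", peaks_per_sample=[len(p) for p in peak_sets])

    # --- consensus + counts -------------------------------------------
    consensus = diffacc.build_consensus(peak_sets, config.consensus_min_samples)
    io.write_intervals(out / "consensus.bed", consensus, "BED6")
    strata = np.array([genome.stratum(r.chrom) for r in consensus])
    counted = diffacc.count_in_regions(
        fragments, consensus,
        truth.samples[["sample_id", "condition", "replicate"]], strata)
    counted.to_frame().to_csv(out / "consensus_counts.tsv", sep="\t", index=False)
    record("consensus_counts", regions=len(consensus))

    # --- differential (stratified + pooled) ---------------------------
    model = diffacc.DifferentialAccessibilityModel(counted)
    model.genome = genome
    results = {}
    for comp, (target, ref) in simulate.COMPARISONS.items():
        for mode in ("stratified", "pooled"):
            res = model.fit(target, ref, mode=mode)
            res.table.to_csv(out / f"da_{comp}_{mode}.tsv", sep="\t", index=False)
            results[(comp, mode)] = res
        res = results[(comp, "stratified")]
        res.manhattan(config.thresholds["da_fdr"]).to_csv(
            out / f"manhattan_{comp}.tsv", sep="\t", index=False)
    record("diff", comparisons=list(simulate.COMPARISONS),
           significant={c: int((r.table["fdr"] < config.thresholds["da_fdr"]).sum())
                        for (c, m), r in results.items() if m == "stratified"})

    # --- specificity --------------------------------------------------
    res1 = results[("fruplus_vs_fruminus_male", "stratified")].table
    res2 = results[("male_vs_female_fruplus", "stratified")].table
    spec_calls = specificity.intersect_classify(
        res1, res2, config.thresholds["da_fdr"])
    spec_calls.to_csv(out / "specificity.tsv", sep="\t", index=False)
    sets = {
        "fruplus_vs_fruminus_male": set(
            res1.loc[res1["fdr"] < config.thresholds["da_fdr"], "region"]),
        "male_vs_female_fruplus": set(
            res2.loc[res2["fdr"] < config.thresholds["da_fdr"], "region"]),
    }
    upset = specificity.upset_counts(sets)
    upset.counts.to_csv(out / "upset.tsv", sep="\t", index=False)
    record("specificity",
           counts=spec_calls["status"].value_counts().to_dict())

    # --- annotate -----------------------------------------------------
    annotation = ann.annotate_peaks(consensus, genes)
    annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
    specific = spec_calls[spec_calls["status"].isin(
        ["opened_in_target", "closed_in_target"])]
    sel_genes = set(annotation.set_index("region").loc[
        specific["region"], "nearest_gene"])
    bg_genes = set(annotation["nearest_gene"])
    record("annotate", classes=annotation["feature_class"].value_counts().to_dict())

    # --- reldist ------------------------------------------------------
    x_regions = [r for r in consensus if genome.stratum(r.chrom) == "X"]
    sig_x = set(res2.loc[(res2["fdr"] < config.thresholds["da_fdr"])
                         & (res2["stratum"] == "X")
                         & (res2["log2fc"] > 0), "region"])
    selection = "fdr"
    if len(sig_x) < 2:  # demo-scale fallback: nominally male-biased X regions
        sig_x = set(res2.loc[(res2["pvalue"] < 0.05)
                             & (res2["stratum"] == "X")
                             & (res2["log2fc"] > 0), "region"])
        selection = "nominal_p"
    male_biased_x = [r for r in x_regions if r.name in sig_x]
    if len(truth.tether_sites) >= 2 and male_biased_x:
        rd = ann.relative_distance(male_biased_x, truth.tether_sites)
        rd.histogram.to_csv(out / "reldist_histogram.tsv", sep="\t", index=False)
        rd.to_frame().to_csv(out / "reldist_values.tsv", sep="\t", index=False)
        record("reldist", n=len(rd.d_values), mean=rd.mean,
               fraction_overlapping=rd.fraction_overlapping_b,
               selection=selection)
    else:
        record("reldist", skipped="no male-biased X regions or <2 tether sites")

    # --- motif --------------------------------------------------------
    hits = motif_mod.scan_fasta(records, pwm)
    hits_df = pd.DataFrame([
        {"region": h.region_id, "class": h.class_label,
         "score_bits": h.score_bits, "pvalue": h.pvalue,
         "position": h.position, "strand": h.strand} for h in hits])
    hits_df.to_csv(out / "motif_best_hits.tsv", sep="\t", index=False)
    comp = motif_mod.class_comparison(hits, config.thresholds["motif_p"])
    comp.ks.to_csv(out / "motif_ks.tsv", sep="\t", index=False)
    comp.fisher.to_csv(out / "motif_fisher.tsv", sep="\t", index=False)
    comp.counts.to_csv(out / "motif_counts.tsv", sep="\t", index=False)
    record("motif", counts=comp.counts.to_dict("records"))

    # --- coverage QC --------------------------------------------------
    corr = cov.sample_correlation(fragments, genome)
    corr.to_csv(out / "sample_correlation.tsv", sep="\t")
    fractions = cov.chrom_read_fractions(fragments, genome)
    fractions.to_csv(out / "chrom_read_fractions.tsv", sep="\t", index=False)
    gene_counts = cov.gene_scale_counts(fragments, genes)
    gene_counts.to_csv(out / "gene_scale_counts.tsv", sep="\t", index=False)
    record("coverage", genes=len(gene_counts))

    # --- rnaseq -------------------------------------------------------
    mfp_ids = truth.samples.loc[
        truth.samples["condition"] == "male_fru_plus", "sample_id"]
    gene_acc = gene_counts[[f"{s}_per_bp" for s in mfp_ids]].mean(axis=1)
    expr_counts, expr_sheet = simulate.simulate_expression(
        n_genes=len(genes), seed=stage_seed(config.seed, "rnaseq"),
        gene_lengths=np.array([g.exonic_length for g in genes]),
        accessibility=gene_acc.to_numpy())
    expr_counts["gene_id"] = [g.gene_id for g in genes]
    sample_ids = list(expr_sheet["sample_id"])
    groups = {c: list(expr_sheet.loc[expr_sheet["condition"] == c, "sample_id"])
              for c in expr_sheet["condition"].unique()}
    tpm_table = rnaseq.tpm(expr_counts, expr_counts["length"], sample_ids, groups)
    tpm_table.to_csv(out / "tpm.tsv", sep="\t", index=False)
    de = rnaseq.de_genes(expr_counts, expr_sheet,
                         "male_fru_plus", "female_fru_plus")
    de.to_csv(out / "de_male_vs_female_fruplus.tsv", sep="\t", index=False)
    acc = pd.Series(gene_acc.to_numpy(), index=gene_counts["gene_id"])
    expr = tpm_table.copy()
    expr.index = expr_counts["gene_id"]
    r2 = cov.accessibility_expression_r2(
        acc, expr["tpm_mean_male_fru_plus"])
    record("rnaseq", genes=len(de), accessibility_expression_r2=r2)

    manifest["wall_time_s"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
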