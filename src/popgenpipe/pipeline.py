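"""Pipeline orchestration over synthetic or user-provided callsets.

Stage order follows the analysis chain: simulation -> genotype/site
filters and artifact-window removal -> per-individual statistics ->
folded spectra and diversity -> demographic model fitting -> DFE ->
comparative conversions.  Every stage writes its outputs to the run
directory and appends a section to a machine-readable summary; stages
communicate through those files, so a failed run can be resumed and
completed stages are skipped.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import callset as cs
from . import comparative as comp
from . import dfe as dfe_mod
from . import popstats, qc, sfs
from .config import PipelineConfig
from .demography import (DemographicModelSpec, compare_models, fit_model,
                         to_physical_units)
from .simulate import (annotate_site_classes, apply_sequencing_noise,
                       simulate_two_pop_coalescent, write_truth)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "stats", "sfs", "demography", "dfe", "comparative")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, checkpoint: Path, cause: Exception):
        self.stage = stage
        self.checkpoint = checkpoint
        super().__init__(
            f"stage {stage!r} failed ({cause}); completed stages are "
            f"checkpointed in {checkpoint} — rerun with resume=True")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not serializable: {type(o)}")


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def run_pipeline(config: PipelineConfig, outdir, resume: bool = False) -> dict:
    """Run the configured stages; returns the summary dictionary."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ckpt_path = outdir / "checkpoint.json"
    summary: dict = {"seed": config.seed, "stages": {}}
    if resume and ckpt_path.exists():
        with open(ckpt_path) as fh:
            summary = json.load(fh)

    runners = {
        "simulate": _stage_simulate, "qc": _stage_qc, "stats": _stage_stats,
        "sfs": _stage_sfs, "demography": _stage_demography, "dfe": _stage_dfe,
        "comparative": _stage_comparative,
    }
    for stage in STAGES:
        if stage not in config.stages:
            continue
        if stage in summary["stages"]:
            logger.info("stage %s already complete; skipping", stage)
            continue
        logger.info("running stage %s", stage)
        try:
            summary["stages"][stage] = runners[stage](config, outdir)
        except Exception as exc:
            _write_json(ckpt_path, summary)
            raise PipelineError(stage, ckpt_path, exc) from exc
        _write_json(ckpt_path, summary)
    _write_json(outdir / "summary.json", summary)
    return summary


# ---------------------------------------------------------------------------
# Stages


def _stage_simulate(config: PipelineConfig, outdir: Path) -> dict:
    sim = config.simulate
    cohort = simulate_two_pop_coalescent(config.demography_model, sim.n1,
                                         sim.n2, seed=config.seed,
                                         num_loci=sim.num_loci)
    classes = annotate_site_classes(cohort, sim.syn_fraction, seed=config.seed,
                                    coding_fraction=sim.coding_fraction,
                                    gene_span=sim.gene_span)
    classes.to_csv(outdir / "site_classes.tsv", sep="\t", index=False)
    annotated, rep_a, rep_b = apply_sequencing_noise(cohort, config.noise)
    contigs = {cohort.chrom: cohort.L}
    cs.write_vcf(annotated, outdir / "cohort.vcf", contigs=contigs)
    cs.write_vcf(rep_a, outdir / "rep_a.vcf", contigs=contigs)
    cs.write_vcf(rep_b, outdir / "rep_b.vcf", contigs=contigs)
    write_truth(cohort, outdir / "truth.tsv", outdir / "truth.json")
    pd.DataFrame({"sample": cohort.samples,
                  "population": cohort.pop_labels}).to_csv(
        outdir / "populations.tsv", sep="\t", index=False)
    return {"n_sites": int(cohort.n_sites), "n_individuals": len(cohort.samples),
            "L": cohort.L, "n_injected_fp": len(cohort.truth["fp_positions"])}


def _stage_qc(config: PipelineConfig, outdir: Path) -> dict:
    callset = cs.read_vcf(outdir / "cohort.vcf")
    rep_a = cs.read_vcf(outdir / "rep_a.vcf")
    rep_b = cs.read_vcf(outdir / "rep_b.vcf")
    with open(outdir / "truth.json") as fh:
        L = int(json.load(fh)["config"]["L"])

    filtered, geno_counts = qc.filter_genotypes(callset, config.genotype_filters)
    report, _ = qc.detect_fp_windows(rep_a, rep_b, genome_bp=L)
    filtered = qc.apply_window_blacklist(filtered, report)
    site_mask, site_counts = qc.filter_sites(filtered, config.site_filters,
                                             stage="heterozygosity")
    het_stage = filtered.take_sites(site_mask)
    cs.write_vcf(het_stage, outdir / "filtered_het_stage.vcf")

    demog_mask, demog_counts = qc.filter_sites(filtered, config.site_filters,
                                               stage="demography")
    thinned = qc.thin_variants(filtered.take_sites(demog_mask))
    cs.write_vcf(thinned, outdir / "thinned_demography.vcf")
    cs.intervals_to_bed([("1", s, e) for s, e in report.blacklisted_windows],
                        outdir / "blacklist.bed")
    counts = pd.concat([
        qc.filter_counts_table(geno_counts).assign(scope="genotype"),
        qc.filter_counts_table(site_counts).assign(scope="site_het_stage"),
        qc.filter_counts_table(demog_counts).assign(scope="site_demog_stage"),
    ])
    counts.to_csv(outdir / "filter_counts.tsv", sep="\t", index=False)
    callable_bp = L * (1.0 - report.genome_removed_fraction)
    return {"genotype_filter_counts": geno_counts,
            "site_filter_counts": site_counts,
            "demography_filter_counts": demog_counts,
            "fp_discarded_fraction": report.fp_discarded_fraction,
            "genome_removed_fraction": report.genome_removed_fraction,
            "n_blacklisted_windows": len(report.blacklisted_windows),
            "callable_bp": callable_bp,
            "n_sites_het_stage": int(het_stage.n_sites),
            "n_sites_thinned": int(thinned.n_sites)}


def _stage_stats(config: PipelineConfig, outdir: Path) -> dict:
    callset = cs.read_vcf(outdir / "filtered_het_stage.vcf")
    callable_bp = run_summary_value(outdir, "qc", "callable_bp")

    het_rows, f_rows, roh_rows = [], [], []
    n_chrom_called = 2 * (callset.gt != cs.MISSING).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(n_chrom_called > 0,
                         np.where(callset.gt == cs.MISSING, 0, callset.gt)
                         .sum(axis=1) / np.maximum(n_chrom_called, 1), 0.0)
    for j, name in enumerate(callset.samples):
        g = callset.gt[:, j]
        het_count = int((g == 1).sum())
        het_rows.append({"sample": name,
                         "het_per_kb": popstats.heterozygosity_per_kb(
                             het_count, callable_bp)})
        try:
            f = popstats.inbreeding_coefficient(g, freqs, n_chrom_called,
                                                individual=name)
            f_rows.append({"sample": name, "F": f.F, "n_sites": f.n_sites})
        except ValueError:
            f_rows.append({"sample": name, "F": float("nan"), "n_sites": 0})
        segs = popstats.detect_roh(callset.pos, g == 1, chrom="1")
        roh_rows += [{"sample": name, "chrom": s.chrom, "start": s.start,
                      "end": s.end, "n_sites": s.n_sites} for s in segs]

    kin_rows = []
    for a in range(callset.n_samples):
        for b in range(a + 1, callset.n_samples):
            try:
                k = popstats.king_kinship(callset.gt[:, a], callset.gt[:, b],
                                          callset.samples[a], callset.samples[b])
                kin_rows.append({"id_i": k.id_i, "id_j": k.id_j, "phi": k.phi,
                                 "shared_sites": k.shared_sites})
            except ValueError:
                pass
    scores, var = popstats.genotype_pca(callset.gt)
    pd.DataFrame(het_rows).to_csv(outdir / "heterozygosity.tsv", sep="\t", index=False)
    pd.DataFrame(f_rows).to_csv(outdir / "inbreeding.tsv", sep="\t", index=False)
    pd.DataFrame(kin_rows).to_csv(outdir / "kinship.tsv", sep="\t", index=False)
    pd.DataFrame(roh_rows).to_csv(outdir / "roh.tsv", sep="\t", index=False)
    pca = pd.DataFrame(scores, columns=[f"PC{i+1}" for i in range(scores.shape[1])])
    pca.insert(0, "sample", callset.samples)
    pca.to_csv(outdir / "pca.tsv", sep="\t", index=False)
    return {"mean_het_per_kb": float(np.mean([r["het_per_kb"] for r in het_rows])),
            "n_roh_segments": len(roh_rows),
            "pca_var_explained": [float(v) for v in var[:5]]}


def _stage_sfs(config: PipelineConfig, outdir: Path) -> dict:
    callset = cs.read_vcf(outdir / "filtered_het_stage.vcf")
    classes = pd.read_csv(outdir / "site_classes.tsv", sep="\t")
    pops = pd.read_csv(outdir / "populations.tsv", sep="\t")
    class_of = dict(zip(classes["pos"], classes["site_class"]))
    site_class = np.asarray([class_of.get(int(p), "other") for p in callset.pos],
                            dtype=object)
    pop_of = dict(zip(pops["sample"], pops["population"]))
    labels = np.asarray([pop_of[s] for s in callset.samples])
    n = 2 * callset.n_samples
    callable_bp = run_summary_value(outdir, "qc", "callable_bp")
    sim = config.simulate
    L_syn = callable_bp * sim.coding_fraction * sim.syn_fraction
    L_nonsyn = callable_bp * sim.coding_fraction * (1.0 - sim.syn_fraction)
    L_syn = max(L_syn, 1.0)
    L_nonsyn = max(L_nonsyn, 1.0)
    syn = sfs.build_folded_sfs(callset.gt, n, site_class == "synonymous", L=L_syn)
    nonsyn = sfs.build_folded_sfs(callset.gt, n, site_class == "nonsynonymous",
                                  L=L_nonsyn)
    syn.to_tsv(outdir / "sfs_synonymous.tsv")
    nonsyn.to_tsv(outdir / "sfs_nonsynonymous.tsv")
    summary = sfs.diversity_summary(syn, nonsyn, L_syn, L_nonsyn)

    thinned = cs.read_vcf(outdir / "thinned_demography.vcf")
    joint = sfs.build_joint_folded_sfs(thinned.gt[:, labels == "pop1"],
                                       thinned.gt[:, labels == "pop2"])
    joint.to_tsv(outdir / "joint_sfs.tsv")
    return {"diversity": {k: (None if isinstance(v, float) and np.isnan(v) else v)
                          for k, v in vars(summary).items()},
            "joint_sfs_total": joint.total,
            "S_syn": syn.segregating_sites, "S_nonsyn": nonsyn.segregating_sites}


def _stage_demography(config: PipelineConfig, outdir: Path) -> dict:
    joint = sfs.FoldedJointSFS.from_tsv(outdir / "joint_sfs.tsv")
    fitcfg = config.demography_fit
    fits = {}
    section = {"fits": {}}
    for kind in fitcfg.models:
        fit = fit_model(joint, DemographicModelSpec(kind),
                        n_replicates=fitcfg.n_replicates, seed=config.seed,
                        grid_size=fitcfg.grid_size, maxiter=fitcfg.maxiter,
                        keep_replicates=False)
        fits[kind] = fit
        section["fits"][kind] = {"params": fit.params, "loglik": fit.loglik,
                                 "aic": fit.aic, "converged": fit.converged}
    if len(fits) > 1:
        cmpres = compare_models(fits)
        cmpres.ranking.to_csv(outdir / "model_ranking.tsv", sep="\t", index=False)
        cmpres.lrt.to_csv(outdir / "model_lrt.tsv", sep="\t", index=False)
        section["best_by_aic"] = cmpres.best_by_aic
        section["am_vs_sc"] = cmpres.am_vs_sc
        best = fits[cmpres.best_by_aic]
    else:
        best = next(iter(fits.values()))
        section["best_by_aic"] = best.kind
    model = config.demography_model
    phys = to_physical_units(best, mu=model.mu, L=model.L, g=model.g)
    section["physical"] = {k: v for k, v in vars(phys).items()}
    _write_json(outdir / "demography_fits.json", section)
    return section


def _stage_dfe(config: PipelineConfig, outdir: Path) -> dict:
    if not config.dfe.enabled:
        return {"skipped": True}
    syn = sfs.FoldedSFS.from_tsv(outdir / "sfs_synonymous.tsv")
    nonsyn = sfs.FoldedSFS.from_tsv(outdir / "sfs_nonsynonymous.tsv")
    fit = dfe_mod.fit_dfe(syn, nonsyn, n_grid=config.dfe.n_grid,
                          n_starts=config.dfe.n_starts, seed=config.seed)
    section = {"shape": fit.gamma.shape, "mean_nes": fit.gamma.mean_nes,
               "nuisance_size_ratio": fit.nuisance_size_ratio,
               "nuisance_change_time": fit.nuisance_change_time,
               "loglik": fit.loglik,
               "bin_edges": [e if np.isfinite(e) else "inf"
                             for e in fit.bin_edges],
               "bin_proportions": [float(p) for p in fit.bin_proportions]}
    _write_json(outdir / "dfe_fit.json", section)
    return section


def _stage_comparative(config: PipelineConfig, outdir: Path) -> dict:
    section: dict = {}
    ccfg = config.comparative
    section["mu_from_divergence"] = comp.mutation_rate_from_divergence(
        ccfg.ds, ccfg.T_split_years, sig_figures=1)
    demog_path = outdir / "demography_fits.json"
    sfs_summary = run_summary_value(outdir, "sfs", "diversity")
    if demog_path.exists() and sfs_summary:
        with open(demog_path) as fh:
            phys = json.load(fh)["physical"]
        pi_s = sfs_summary.get("pi_syn")
        if pi_s and pi_s > 0 and phys["N1"] > 0:
            n_current = 0.5 * (phys["N1"] + phys["N2"])
            section["pi_ancestral_rescaled"] = comp.rescale_ancestral_diversity(
                pi_s, n_current, phys["N_anc"])
    if ccfg.life_history_csv:
        records = pd.read_csv(ccfg.life_history_csv)
        loadings = (comp.FactorLoadings.from_yaml(ccfg.loadings_yaml)
                    if ccfg.loadings_yaml else None)
        factors = comp.mass_residual_factors(records, loadings)
        factors.to_csv(outdir / "life_history_factors.tsv", sep="\t", index=False)
        section["n_species_factors"] = int(len(factors))
    if ccfg.diversity_csv:
        table = pd.read_csv(ccfg.diversity_csv)
        reg = comp.propagule_diversity_regression(table)
        section["propagule_regression"] = {"slope": reg.with_all.slope,
                                           "intercept": reg.with_all.intercept}
    _write_json(outdir / "comparative.json", section)
    return section


def run_summary_value(outdir: Path, stage: str, key: str):
    """Fetch a value recorded by an earlier stage from the checkpoint."""
    with open(Path(outdir) / "checkpoint.json") as fh:
        summary = json.load(fh)
    return summary["stages"][stage][key]
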