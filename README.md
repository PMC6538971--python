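# popgenpipe

A tested, reusable population-genomic inference pipeline for diploid
genotype callsets from two populations: genotype/site quality control,
heterozygosity / runs-of-homozygosity / kinship statistics, folded 1-D
and joint 2-D site-frequency spectra, four-model two-population
demographic inference (SI / IM / AM / SC), gamma distribution-of-fitness-
effects estimation, and a comparative life-history / diversity layer.
A built-in structured-coalescent simulator generates synthetic cohorts
with known truth records so every stage is testable without external
data.

## Layout

| Module | Contents |
| --- | --- |
| `popgenpipe.simulate` | event-driven structured coalescent (split + epoch-dependent migration), sequencing-noise layer, clustered artifact injection, site-class annotation, truth records |
| `popgenpipe.callset` | `GenotypeCallset`, VCF v4.2 read (cyvcf2) / write, BED coordinate conversions |
| `popgenpipe.qc` | genotype filters (depth, allele balance, GQ), stage-specific site filters and hard filters, replicate-based false-positive window blacklisting (5-kb grid), per-window SNP thinning (20 kb) |
| `popgenpipe.popstats` | heterozygosity per kb, two-state HMM RoH detection, KING-style robust kinship, inbreeding coefficients, genotype PCA |
| `popgenpipe.sfs` | folded spectra with hypergeometric projection, joint folded SFS (default 0..4 per axis), Watterson's theta, pi, Tajima's D, pi_N/pi_S |
| `popgenpipe.demography` | exact expected joint SFS under SI/IM/AM/SC (lineage-configuration Markov chain, uniformization), Poisson composite likelihood, multi-start fitting, LRT/AIC model comparison, physical-unit conversion |
| `popgenpipe.dfe` | two-epoch neutral reference, selected spectra from diffusion sojourn integrals, gamma-DFE fitting with Nes bin proportions |
| `popgenpipe.comparative` | life-history two-factor projection, propagule-size diversity regression, ancestral-diversity rescaling, divergence-based mutation rate |
| `popgenpipe.pipeline` / `cli` | stage orchestration with checkpoint/resume, YAML config, `popgenpipe` CLI |

## CLI

```sh
popgenpipe simulate --model AM --n1 4 --n2 4 --t-split 0.8 --t-change 0.08 \
    --m12 4 --m21 1 --out runs/sim
popgenpipe qc runs/sim/cohort.vcf --rep-a runs/sim/rep_a.vcf \
    --rep-b runs/sim/rep_b.vcf --out runs/filtered.vcf
popgenpipe sfs runs/filtered.vcf --out runs/folded.tsv
popgenpipe demog fit runs/joint.tsv --model AM --replicates 50 --seed 1
popgenpipe dfe fit --syn runs/sfs_syn.tsv --nonsyn runs/sfs_nonsyn.tsv
popgenpipe lifehist factors lifehistory.csv --out factors.tsv
popgenpipe run --out runs/full --seed 1        # full synthetic chain
```

`popgenpipe run` executes the whole chain on simulated data and writes a
machine-readable `summary.json`; re-running with the same seed produces a
byte-identical summary, and `--resume` continues a failed run from its
checkpoint.

## Conventions

- Time is scaled in units of 2·N_anc generations; `theta = 4·N_anc·mu·L`;
  `m12`/`m21` are scaled per-lineage backward migration rates.  `AM`
  means migration until `T_change` before the present (then none);
  `SC` means migration only since `T_change`.
- Folded joint spectra project each population to 4 chromosomes by
  hypergeometric down-sampling, then fold on the combined minor allele;
  fold-diagonal cells are split evenly with their complement and flagged.
- Window grids (artifact blacklisting, thinning) are anchored at
  coordinate 1 and half-open; VCF positions are 1-based, emitted BED is
  0-based half-open.

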