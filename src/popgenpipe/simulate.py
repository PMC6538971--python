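"""Synthetic two-population genotype data with known truth.

An event-driven structured coalescent generates genealogies for samples
drawn from two populations that descend from a split, with migration
active only in the epochs that the chosen model dictates (SI, IM, AM,
SC).  Infinite-sites mutations are dropped on branches and genotypes are
formed by random pairing of chromosomes within populations.  A separate
noise layer adds read-depth / allele-balance / genotype-quality fields
and injects clustered artifact SNPs into designated 5-kb windows of two
replicate callsets of one individual, recording everything in a truth
record so downstream filters can be scored exactly.

Time is measured in units of 2*N_anc generations throughout; the pair
coalescence rate in daughter population d is 1/nu_d, and m12 (m21) is
the scaled backward migration rate per lineage from population 1 to 2
(2 to 1).  theta = 4*N_anc*mu*L.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .callset import GenotypeCallset, MISSING

MODEL_KINDS = ("SI", "IM", "AM", "SC")

SUBSTREAMS = ("genealogy", "mutation", "positions", "pairing", "alleles",
              "depth_annot", "depth_rep_a", "depth_rep_b", "balance",
              "info", "fp", "classes")


@dataclass
class DemographyConfig:
    """Two-population split demography with epoch-dependent migration."""

    model_kind: str = "IM"
    N_anc: float = 10_000.0
    nu1: float = 1.0
    nu2: float = 1.0
    T_split: float = 1.0
    T_change: float = 0.0
    m12: float = 0.0
    m21: float = 0.0
    mu: float = 2e-9
    L: int = 1_000_000
    g: float = 5.0

    def validate(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        for name in ("N_anc", "nu1", "nu2", "T_split", "T_change",
                     "m12", "m21", "mu", "L", "g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.model_kind in ("AM", "SC") and not (0 <= self.T_change <= self.T_split):
            raise ValueError("T_change must lie in [0, T_split]")
        if self.model_kind == "SI" and (self.m12 != 0 or self.m21 != 0):
            raise ValueError("SI requires m12 = m21 = 0")

    @property
    def theta(self) -> float:
        return 4.0 * self.N_anc * self.mu * self.L

    def epochs(self) -> list[tuple[float, float, float, float, float]]:
        """Backward-time epochs as (t_end, nu1, nu2, m12, m21) before the
        ancestral merge at T_split; migration activity per model kind:

        - SI: never; IM: throughout [0, T_split];
        - AM: migration ceased T_change ago -> active on [T_change, T_split];
        - SC: migration began T_change ago -> active on [0, T_change].
        """
        nu1, nu2, Ts, Tc = self.nu1, self.nu2, self.T_split, self.T_change
        if self.model_kind == "SI":
            return [(Ts, nu1, nu2, 0.0, 0.0)]
        if self.model_kind == "IM":
            return [(Ts, nu1, nu2, self.m12, self.m21)]
        if self.model_kind == "AM":
            return [(Tc, nu1, nu2, 0.0, 0.0), (Ts, nu1, nu2, self.m12, self.m21)]
        # SC
        return [(Tc, nu1, nu2, self.m12, self.m21), (Ts, nu1, nu2, 0.0, 0.0)]


@dataclass
class NoiseConfig:
    """Sequencing-noise and artifact-injection parameters."""

    mean_depth: float = 20.0
    depth_dispersion: float = 0.0
    balance_noise: float = 0.0
    gq_floor: int = 0
    gq_ceiling: int = 99
    fp_window_count: int = 0
    fp_per_window: int = 0
    fp_window_bp: int = 5_000
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.balance_noise <= 1.0:
            raise ValueError("balance_noise must be a probability")
        if self.fp_per_window < 0 or self.fp_window_count < 0:
            raise ValueError("artifact counts must be non-negative")
        if self.mean_depth < 0 or self.depth_dispersion < 0:
            raise ValueError("depth parameters must be non-negative")


@dataclass
class SimulatedCohort:
    """Genotype matrix with positions, site classes and a truth record."""

    genotypes: np.ndarray          # (n_sites, n_individuals) int8, 0/1/2/-1
    positions: np.ndarray          # 1-based, strictly increasing
    L: int
    samples: list[str]
    pop_labels: list[str]
    chrom: str = "1"
    site_classes: np.ndarray | None = None
    gene_ids: np.ndarray | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotypes must be 0/1/2 or missing")

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    def population_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.pop_labels) == label)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    """Named independent substreams derived from one global seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(SUBSTREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(SUBSTREAMS, children)}


# ---------------------------------------------------------------------------
# Structured coalescent core


def sample_genealogy(rng: np.random.Generator, n1: int, n2: int,
                     config: DemographyConfig):
    """Sample one genealogy; return (branches, tmrca).

    ``branches`` is a list of (descendant-bitmask, i, j, length) with i/j
    the number of population-1/-2 sampled chromosomes below the branch;
    bit k of the mask marks chromosome k (population 1 first).  Lengths
    and tmrca are in units of 2*N_anc generations.
    """
    k1, k2 = 2 * n1, 2 * n2
    # lineage: [deme, mask, i, j, birth_time]
    lineages = [[0, 1 << b, 1, 0, 0.0] for b in range(k1)]
    lineages += [[1, 1 << (k1 + b), 0, 1, 0.0] for b in range(k2)]
    epochs = config.epochs()
    branches = []
    t = 0.0
    ei = 0
    merged = False
    while len(lineages) > 1:
        if not merged and ei < len(epochs):
            t_end, nu1, nu2, m12, m21 = epochs[ei]
        else:
            t_end, nu1, nu2, m12, m21 = math.inf, 1.0, 1.0, 0.0, 0.0
        kd = [0, 0]
        for lin in lineages:
            kd[lin[0]] += 1
        rate_c1 = kd[0] * (kd[0] - 1) / 2.0 / nu1 if nu1 > 0 else 0.0
        rate_c2 = kd[1] * (kd[1] - 1) / 2.0 / nu2 if nu2 > 0 else 0.0
        rate_m12 = kd[0] * m12
        rate_m21 = kd[1] * m21
        total = rate_c1 + rate_c2 + rate_m12 + rate_m21
        if total <= 0.0:
            t_next = math.inf
        else:
            t_next = t + rng.exponential(1.0 / total)
        if t_next >= t_end:
            t = t_end
            ei += 1
            if not merged and t >= config.T_split:
                merged = True
                for lin in lineages:
                    lin[0] = 0
            continue
        t = t_next
        u = rng.uniform() * total
        if u < rate_c1 + rate_c2:
            deme = 0 if u < rate_c1 else 1
            members = [i for i, lin in enumerate(lineages) if lin[0] == deme]
            ia, ib = rng.choice(len(members), size=2, replace=False)
            a, b = sorted((members[ia], members[ib]))
            la, lb = lineages[a], lineages[b]
            for lin in (la, lb):
                branches.append((lin[1], lin[2], lin[3], t - lin[4]))
            merged_lin = [deme, la[1] | lb[1], la[2] + lb[2], la[3] + lb[3], t]
            lineages = [lin for i, lin in enumerate(lineages) if i not in (a, b)]
            lineages.append(merged_lin)
        elif u < rate_c1 + rate_c2 + rate_m12:
            members = [i for i, lin in enumerate(lineages) if lin[0] == 0]
            lineages[members[rng.integers(len(members))]][0] = 1
        else:
            members = [i for i, lin in enumerate(lineages) if lin[0] == 1]
            lineages[members[rng.integers(len(members))]][0] = 0
    return branches, t


def sample_tmrca(config: DemographyConfig, n1: int, n2: int, n_reps: int,
                 seed: int) -> np.ndarray:
    """Monte-Carlo sample of TMRCA in generations."""
    config.validate()
    rng = np.random.default_rng(seed)
    out = np.empty(n_reps)
    for r in range(n_reps):
        _, t = sample_genealogy(rng, n1, n2, config)
        out[r] = t * 2.0 * config.N_anc
    return out


def branch_type_lengths(config: DemographyConfig, n1: int, n2: int,
                        n_reps: int, seed: int) -> np.ndarray:
    """Mean total branch length subtending (i, j) sampled chromosomes.

    Returns a (2*n1+1, 2*n2+1) matrix of Monte-Carlo means; multiplying
    by theta/2 gives the expected unfolded joint SFS.  Serves as the
    simulation oracle for the deterministic expected-SFS engine.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    acc = np.zeros((2 * n1 + 1, 2 * n2 + 1))
    for _ in range(n_reps):
        branches, _ = sample_genealogy(rng, n1, n2, config)
        for _, i, j, length in branches:
            acc[i, j] += length
    return acc / n_reps


# ---------------------------------------------------------------------------
# Cohort simulation


def simulate_two_pop_coalescent(config: DemographyConfig, n1: int, n2: int,
                                seed: int, num_loci: int = 100) -> SimulatedCohort:
    """Simulate diploid genotypes for n1 + n2 individuals.

    The sequence of length ``config.L`` is split into ``num_loci``
    independent non-recombining loci (free recombination between loci,
    none within); mutations are Poisson on branches at theta/2 per unit
    branch length per locus.
    """
    config.validate()
    if n1 < 0 or n2 < 0 or n1 + n2 < 1:
        raise ValueError("need at least one sampled individual")
    rngs = _rngs(seed)
    k = 2 * (n1 + n2)
    n_ind = n1 + n2
    loc_bounds = np.linspace(0, config.L, num_loci + 1).astype(np.int64)
    theta_per_bp = 4.0 * config.N_anc * config.mu

    # random pairing of chromosomes into individuals, within populations
    perm1 = rngs["pairing"].permutation(2 * n1)
    perm2 = rngs["pairing"].permutation(2 * n2) + 2 * n1
    chrom_of = np.concatenate([perm1, perm2]).astype(np.int64)

    pos_all, gt_all = [], []
    for loc in range(num_loci):
        lo, hi = loc_bounds[loc], loc_bounds[loc + 1]
        span = int(hi - lo)
        if span <= 0:
            continue
        branches, _ = sample_genealogy(rngs["genealogy"], n1, n2, config)
        theta_loc = theta_per_bp * span
        masks = []
        for mask, i, j, length in branches:
            if i + j == k:  # branch above the last coalescence: not polymorphic
                continue
            n_mut = rngs["mutation"].poisson(0.5 * theta_loc * length)
            masks.extend([mask] * int(n_mut))
        n_sites = min(len(masks), span)
        if n_sites == 0:
            continue
        pos = np.sort(rngs["positions"].choice(span, size=n_sites, replace=False)) + lo + 1
        gt = np.empty((n_sites, n_ind), dtype=np.int8)
        for s, mask in enumerate(masks[:n_sites]):
            bits = np.fromiter(((mask >> int(b)) & 1 for b in chrom_of),
                               count=k, dtype=np.int8)
            gt[s] = bits[0::2] + bits[1::2]
        pos_all.append(pos)
        gt_all.append(gt)

    if pos_all:
        positions = np.concatenate(pos_all)
        genotypes = np.vstack(gt_all)
    else:
        positions = np.empty(0, dtype=np.int64)
        genotypes = np.zeros((0, n_ind), dtype=np.int8)
    samples = [f"pop1_{i}" for i in range(n1)] + [f"pop2_{i}" for i in range(n2)]
    pop_labels = ["pop1"] * n1 + ["pop2"] * n2
    truth = {
        "config": asdict(config), "seed": seed, "n1": n1, "n2": n2,
        "num_loci": num_loci, "fp_positions": [], "fp_windows": [],
        "roh_tracts": [],
    }
    return SimulatedCohort(genotypes=genotypes, positions=positions,
                           L=int(config.L), samples=samples,
                           pop_labels=pop_labels, truth=truth)


def plant_roh_tract(cohort: SimulatedCohort, individual: int,
                    start: int, end: int) -> None:
    """Force genotypes of one individual to homozygous reference inside
    [start, end] (1-based inclusive) and record the tract in the truth."""
    if not (1 <= start <= end <= cohort.L):
        raise ValueError("tract must lie within [1, L]")
    in_tract = (cohort.positions >= start) & (cohort.positions <= end)
    cohort.genotypes[in_tract, individual] = 0
    cohort.truth["roh_tracts"].append(
        {"individual": individual, "start": int(start), "end": int(end)})


# ---------------------------------------------------------------------------
# Site-class annotation


def annotate_site_classes(cohort: SimulatedCohort, syn_fraction: float,
                          seed: int, coding_fraction: float = 1.0,
                          gene_span: int = 10_000) -> pd.DataFrame:
    """Label each variant synonymous / nonsynonymous / other.

    A site is coding with probability ``coding_fraction``; coding sites
    are synonymous with probability ``syn_fraction``.  Genes are
    contiguous ``gene_span``-bp blocks, giving the per-gene grouping
    used for gene-by-gene folded spectra.
    """
    if not 0.0 <= syn_fraction <= 1.0:
        raise ValueError("syn_fraction must be in [0, 1]")
    if not 0.0 <= coding_fraction <= 1.0:
        raise ValueError("coding_fraction must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = cohort.n_sites
    u = rng.uniform(size=n)
    v = rng.uniform(size=n)
    classes = np.where(u >= coding_fraction, "other",
                       np.where(v < syn_fraction, "synonymous", "nonsynonymous"))
    gene_ids = np.asarray([f"g{(p - 1) // gene_span}" for p in cohort.positions],
                          dtype=object)
    cohort.site_classes = classes.astype(object)
    cohort.gene_ids = gene_ids
    return pd.DataFrame({"chrom": cohort.chrom, "pos": cohort.positions,
                         "site_class": classes, "gene_id": gene_ids})


# ---------------------------------------------------------------------------
# Sequencing noise and artifact injection


def _gq_from_ad(dp: np.ndarray, ad_alt: np.ndarray, floor: int, ceiling: int):
    """Phred margin between best and second-best binomial genotype
    likelihood (alt-read fractions 0.02 / 0.5 / 0.98); deterministic."""
    dp = dp.astype(float)
    a = ad_alt.astype(float)
    r = dp - a
    with np.errstate(divide="ignore", invalid="ignore"):
        lls = np.stack([
            a * math.log(0.02) + r * math.log(0.98),
            a * math.log(0.5) + r * math.log(0.5),
            a * math.log(0.98) + r * math.log(0.02),
        ])
    lls = np.sort(lls, axis=0)
    margin = (lls[-1] - lls[-2]) * (10.0 / math.log(10.0))
    gq = np.clip(np.round(margin), floor, ceiling).astype(np.int32)
    gq[dp <= 0] = floor
    return gq


def _depths(rng, shape, noise: NoiseConfig) -> np.ndarray:
    if noise.depth_dispersion <= 0:
        return np.full(shape, int(round(noise.mean_depth)), dtype=np.int32)
    # negative binomial via gamma-Poisson: var = mean + disp * mean^2
    shape_par = 1.0 / noise.depth_dispersion
    lam = rng.gamma(shape_par, noise.mean_depth * noise.depth_dispersion, size=shape)
    return rng.poisson(lam).astype(np.int32)


def _format_fields(gt: np.ndarray, dp: np.ndarray, rng_balance,
                   noise: NoiseConfig):
    """AD split and GQ for a genotype matrix given depths."""
    ad_alt = np.where(gt == 2, dp, 0).astype(np.int32)
    het = gt == 1
    ad_alt[het] = (dp[het] - dp[het] // 2)
    if noise.balance_noise > 0 and het.any():
        distort = rng_balance.uniform(size=int(het.sum())) < noise.balance_noise
        skewed = rng_balance.binomial(dp[het], 0.12).astype(np.int32)
        ad_alt[het] = np.where(distort, skewed, ad_alt[het])
    ad_alt = np.minimum(ad_alt, dp)
    ad_ref = (dp - ad_alt).astype(np.int32)
    gq = _gq_from_ad(dp, ad_alt, noise.gq_floor, noise.gq_ceiling)
    miss = gt == MISSING
    for arr in (ad_ref, ad_alt, gq):
        arr[miss] = MISSING
    dp = dp.copy()
    dp[miss] = MISSING
    return dp, ad_ref, ad_alt, gq


def _site_annotations(rng, n_sites: int):
    """Per-site QUAL and INFO annotations drawn from passing ranges."""
    qual = rng.uniform(100.0, 2000.0, size=n_sites)
    info = {
        "QD": rng.uniform(5.0, 30.0, size=n_sites),
        "SOR": rng.uniform(0.3, 2.5, size=n_sites),
        "MQ": rng.uniform(52.0, 60.0, size=n_sites),
        "MQRankSum": rng.uniform(-1.5, 0.4, size=n_sites),
        "ReadPosRankSum": rng.uniform(-1.5, 1.5, size=n_sites),
    }
    return qual, info


_BASES = np.array(list("ACGT"), dtype=object)


def apply_sequencing_noise(cohort: SimulatedCohort, noise: NoiseConfig):
    """Produce an annotated cohort callset plus two replicate callsets of
    the reference individual with injected artifact SNPs.

    Returns ``(annotated, replicate_a, replicate_b)``; the cohort truth
    record gains the injected FP positions and designated windows.
    """
    noise.validate()
    rngs = _rngs(noise.seed)
    n_sites, n_ind = cohort.genotypes.shape

    # designated artifact windows on the 5-kb grid anchored at 1
    wsize = noise.fp_window_bp
    n_windows = -(-cohort.L // wsize)
    if noise.fp_window_count > n_windows:
        raise ValueError(
            f"fp_window_count={noise.fp_window_count} exceeds the "
            f"{n_windows} available {wsize}-bp windows")
    fp_pos: list[int] = []
    fp_windows: list[int] = []
    if noise.fp_window_count > 0 and noise.fp_per_window > 0:
        windows = np.sort(rngs["fp"].choice(n_windows, size=noise.fp_window_count,
                                            replace=False))
        taken = set(int(p) for p in cohort.positions)
        for w in windows:
            lo = int(w) * wsize + 1
            hi = min(lo + wsize - 1, cohort.L)
            avail = [p for p in range(lo, hi + 1) if p not in taken]
            if len(avail) < noise.fp_per_window:
                raise ValueError(f"window {w} too full to hold artifact SNPs")
            chosen = rngs["fp"].choice(len(avail), size=noise.fp_per_window,
                                       replace=False)
            for c in chosen:
                fp_pos.append(avail[int(c)])
                taken.add(avail[int(c)])
            fp_windows.append(int(w))
    fp_pos = sorted(fp_pos)
    cohort.truth["fp_positions"] = fp_pos
    cohort.truth["fp_windows"] = fp_windows

    # union site list for the replicate callsets
    rep_pos = np.sort(np.concatenate([cohort.positions,
                                      np.asarray(fp_pos, dtype=np.int64)]))
    is_fp = np.isin(rep_pos, np.asarray(fp_pos, dtype=np.int64))
    cohort_sites = ~is_fp

    # REF/ALT alleles, shared everywhere
    ref = _BASES[rngs["alleles"].integers(0, 4, size=rep_pos.size)]
    shift = rngs["alleles"].integers(1, 4, size=rep_pos.size)
    alt = _BASES[(np.searchsorted(_BASES, ref) + shift) % 4]
    qual, info = _site_annotations(rngs["info"], rep_pos.size)

    def subset(arr):
        return arr[cohort_sites]

    # annotated multi-individual callset (cohort sites only)
    gt_annot = cohort.genotypes
    dp_annot = _depths(rngs["depth_annot"], gt_annot.shape, noise)
    dp_a_, ar_, aa_, gq_ = _format_fields(gt_annot, dp_annot, rngs["balance"], noise)
    annotated = GenotypeCallset(
        chrom=np.full(n_sites, cohort.chrom, dtype=object),
        pos=cohort.positions,
        ref=subset(ref), alt=subset(alt),
        gt=gt_annot, samples=list(cohort.samples),
        dp=dp_a_, ad_ref=ar_, ad_alt=aa_, gq=gq_,
        qual=subset(qual), info={k: subset(v) for k, v in info.items()},
    )

    # replicate callsets of the reference individual (index 0)
    base_gt = np.zeros(rep_pos.size, dtype=np.int8)
    base_gt[cohort_sites] = cohort.genotypes[:, 0]
    reps = []
    for name, fp_gt in (("depth_rep_a", 0), ("depth_rep_b", 2)):
        gt = base_gt.copy()
        gt[is_fp] = fp_gt
        gt = gt[:, None]
        dp = _depths(rngs[name], gt.shape, noise)
        dp_, ar, aa, gq = _format_fields(gt, dp, rngs["balance"], noise)
        reps.append(GenotypeCallset(
            chrom=np.full(rep_pos.size, cohort.chrom, dtype=object),
            pos=rep_pos, ref=ref.copy(), alt=alt.copy(),
            gt=gt, samples=[cohort.samples[0]],
            dp=dp_, ad_ref=ar, ad_alt=aa, gq=gq,
            qual=qual.copy(), info={k: v.copy() for k, v in info.items()},
        ))
    return annotated, reps[0], reps[1]


# ---------------------------------------------------------------------------
# Expected-SFS sampling


def sample_sfs_counts(expected, seed: int):
    """Independent Poisson draws around an expected spectrum.

    Accepts a plain array (returns an array) or an object exposing
    ``data``/``mask`` (masked cells stay zero; returns the same type).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if hasattr(expected, "data") and hasattr(expected, "mask"):
        exp = np.asarray(expected.data, dtype=float)
        if np.any(exp[~expected.mask] < 0) or not np.all(np.isfinite(exp[~expected.mask])):
            raise ValueError("expected SFS must be finite and non-negative")
        out = expected.copy()
        drawn = rng.poisson(np.where(expected.mask, 0.0, exp)).astype(float)
        out.data = np.where(expected.mask, 0.0, drawn)
        return out
    exp = np.asarray(expected, dtype=float)
    if np.any(exp < 0) or not np.all(np.isfinite(exp)):
        raise ValueError("expected SFS must be finite and non-negative")
    return rng.poisson(exp).astype(float)


# ---------------------------------------------------------------------------
# Truth-record serialization


def write_truth(cohort: SimulatedCohort, tsv_path, json_path) -> None:
    """Write the truth record as a TSV of injected FP positions plus a
    JSON sidecar with the full record."""
    df = pd.DataFrame({"chrom": cohort.chrom,
                       "pos": cohort.truth.get("fp_positions", [])})
    df.to_csv(tsv_path, sep="\t", index=False)
    with open(json_path, "w") as fh:
        json.dump(cohort.truth, fh, indent=2, default=float)
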