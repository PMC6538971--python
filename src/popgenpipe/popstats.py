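"""Per-individual and pairwise statistics: heterozygosity, runs of
homozygosity, robust kinship, inbreeding coefficients and genotype PCA."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .callset import MISSING


@dataclass
class RoHSegment:
    chrom: str
    start: int          # bp, 1-based inclusive
    end: int            # bp, 1-based inclusive
    n_sites: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("RoH segment must have end > start")


@dataclass
class KinshipEstimate:
    id_i: str
    id_j: str
    phi: float
    shared_sites: int


@dataclass
class InbreedingEstimate:
    individual: str
    F: float
    observed_hom: float
    expected_hom: float
    n_sites: int


def heterozygosity_per_kb(het_count: int, callable_bp: float) -> float:
    """Heterozygous sites per kilobase of callable sequence."""
    if callable_bp <= 0:
        raise ValueError("callable_bp must be positive")
    return 1000.0 * het_count / callable_bp


def detect_roh(pos: np.ndarray, is_het: np.ndarray, chrom: str = "1",
               p_het_nonroh: float | None = None, p_het_roh: float = 1e-3,
               switch_rate: float = 1e-7,
               min_length: float = 2_000_000) -> list[RoHSegment]:
    """Two-state HMM (RoH vs non-RoH) decoded by the Viterbi path.

    Emissions are heterozygote probabilities per state; transitions
    between consecutive sites at distance d occur with probability
    1 - exp(-switch_rate * d).  ``p_het_nonroh`` defaults to the
    genome-wide heterozygous fraction of the input.  Only segments
    strictly longer than ``min_length`` bp are reported (pass 0 to get
    all decoded segments).
    """
    pos = np.asarray(pos, dtype=np.int64)
    is_het = np.asarray(is_het, dtype=bool)
    if pos.size != is_het.size:
        raise ValueError("pos and is_het must align")
    if pos.size < 2:
        warnings.warn("fewer than 2 informative sites; no RoH called")
        return []
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted")
    if p_het_nonroh is None:
        p_het_nonroh = max(float(is_het.mean()), 1e-6)
    p_het_nonroh = min(max(p_het_nonroh, 1e-9), 1 - 1e-9)
    p_het_roh = min(max(p_het_roh, 1e-9), 1 - 1e-9)

    # state 0 = non-RoH, state 1 = RoH
    log_emit = np.empty((pos.size, 2))
    log_emit[:, 0] = np.where(is_het, math.log(p_het_nonroh),
                              math.log1p(-p_het_nonroh))
    log_emit[:, 1] = np.where(is_het, math.log(p_het_roh),
                              math.log1p(-p_het_roh))

    d = np.diff(pos).astype(float)
    p_switch = np.clip(1.0 - np.exp(-switch_rate * d), 1e-12, 0.5)
    log_stay = np.log1p(-p_switch)
    log_sw = np.log(p_switch)

    n = pos.size
    delta = log_emit[0] + math.log(0.5)
    back = np.zeros((n, 2), dtype=np.int8)
    for t in range(1, n):
        for s in range(2):
            cand = delta + np.where(np.arange(2) == s, log_stay[t - 1], log_sw[t - 1])
            back[t, s] = int(np.argmax(cand))
            log_emit[t, s] += cand[back[t, s]]
        delta = log_emit[t]
    states = np.empty(n, dtype=np.int8)
    states[-1] = int(np.argmax(delta))
    for t in range(n - 2, -1, -1):
        states[t] = back[t + 1, states[t + 1]]

    segments: list[RoHSegment] = []
    i = 0
    while i < n:
        if states[i] == 1:
            j = i
            while j + 1 < n and states[j + 1] == 1:
                j += 1
            seg = RoHSegment(chrom=chrom, start=int(pos[i]), end=int(pos[j]),
                             n_sites=j - i + 1) if pos[j] > pos[i] else None
            if seg is not None and seg.length > min_length:
                segments.append(seg)
            i = j + 1
        else:
            i += 1
    return segments


def king_kinship(genotypes_i: np.ndarray, genotypes_j: np.ndarray,
                 id_i: str = "i", id_j: str = "j") -> KinshipEstimate:
    """Robust pairwise kinship from joint genotype counts.

    phi = (N_het,het - 2 * N_opposite-hom) / (N_het,i + N_het,j) over
    jointly non-missing biallelic sites; the symmetric denominator keeps
    phi(i, j) = phi(j, i).  Self comparison gives exactly 0.5.
    """
    gi = np.asarray(genotypes_i)
    gj = np.asarray(genotypes_j)
    both = (gi != MISSING) & (gj != MISSING)
    if not both.any():
        raise ValueError("no jointly called sites")
    gi, gj = gi[both], gj[both]
    n_het_i = int((gi == 1).sum())
    n_het_j = int((gj == 1).sum())
    if n_het_i + n_het_j == 0:
        raise ValueError("zero heterozygotes in both individuals; "
                         "kinship undefined")
    n_hh = int(((gi == 1) & (gj == 1)).sum())
    n_opp = int((((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))).sum())
    phi = (n_hh - 2.0 * n_opp) / (n_het_i + n_het_j)
    return KinshipEstimate(id_i=id_i, id_j=id_j, phi=phi,
                           shared_sites=int(both.sum()))


def inbreeding_coefficient(genotypes: np.ndarray, allele_freqs: np.ndarray,
                           n_alleles, individual: str = "i") -> InbreedingEstimate:
    """Method-of-moments F from observed vs expected homozygosity.

    ``allele_freqs`` are pooled-sample alternate-allele frequencies and
    ``n_alleles`` the pooled haploid sample size per site (scalar or
    array).  Expected homozygosity uses the small-sample correction
    E_hom = sum over sites of 1 - 2 p (1-p) n/(n-1), and
    F = (O_hom - E_hom) / (N - E_hom).
    """
    g = np.asarray(genotypes)
    p = np.asarray(allele_freqs, dtype=float)
    n = np.broadcast_to(np.asarray(n_alleles, dtype=float), p.shape)
    called = g != MISSING
    usable = called & (n > 1)
    if not usable.any():
        raise ValueError("no usable sites")
    g, p, n = g[usable], p[usable], n[usable]
    o_hom = float(((g == 0) | (g == 2)).sum())
    e_hom = float(np.sum(1.0 - 2.0 * p * (1.0 - p) * n / (n - 1.0)))
    n_sites = int(usable.sum())
    if abs(n_sites - e_hom) < 1e-12:
        raise ValueError("degenerate: expected homozygosity equals site count")
    F = (o_hom - e_hom) / (n_sites - e_hom)
    return InbreedingEstimate(individual=individual, F=F, observed_hom=o_hom,
                              expected_hom=e_hom, n_sites=n_sites)


def genotype_pca(genotypes: np.ndarray, include_singletons: bool = True,
                 n_components: int | None = None):
    """PCA of a sites x individuals genotype matrix via SVD.

    Missing genotypes are mean-imputed per site before column-centering.
    Returns (scores, variance_explained) with individuals as rows.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2 or g.shape[1] < 2 or g.shape[0] < 1:
        raise ValueError("need >= 2 individuals and >= 1 variant")
    g = g.copy()
    g[g == MISSING] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        site_mean = np.nanmean(g, axis=1)
    site_mean = np.nan_to_num(site_mean)
    inds = np.where(np.isnan(g), site_mean[:, None], g)
    if not include_singletons:
        alt = inds.sum(axis=1)
        n_chrom = 2 * g.shape[1]
        mac = np.minimum(alt, n_chrom - alt)
        inds = inds[mac > 1]
        if inds.shape[0] == 0:
            raise ValueError("no variants left after singleton removal")
    X = inds.T - inds.mean(axis=1)  # individuals x sites, column-centered
    if np.allclose(X, 0.0):
        warnings.warn("constant genotype matrix: all component scores zero")
        k = n_components or min(X.shape)
        return np.zeros((X.shape[0], k)), np.zeros(k)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = u * s
    var = s ** 2 / np.sum(s ** 2)
    if n_components is not None:
        scores, var = scores[:, :n_components], var[:n_components]
    return scores, var
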