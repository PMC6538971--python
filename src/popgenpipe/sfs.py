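"""Folded one- and two-dimensional site frequency spectra.

Conventions
-----------
* Folded 1-D spectra index minor-allele counts 1..floor(n/2); bin 0
  holds monomorphic mass and is ignored by the statistics.
* Sites with missing genotypes are hypergeometrically down-projected
  from their observed allele number to the target sample size; sites
  observed below the target are dropped.
* The joint spectrum projects each population to n_eff chromosomes
  (default 4) and folds on the combined minor allele; cells on the
  fold diagonal (i + j exactly half) are split evenly with their
  complement and flagged; folded-away cells and (0, 0) are masked.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .callset import MISSING


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def projection_matrix(n_from: int, n_to: int) -> np.ndarray:
    """Hypergeometric down-projection: P[d, k] = P(k of n_to | d of n_from).

    Expectation-preserving and linear in the input spectrum.
    """
    if n_to > n_from:
        raise ValueError("cannot project upward")
    d = np.arange(n_from + 1)[:, None]
    k = np.arange(n_to + 1)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = (_log_comb(d, k) + _log_comb(n_from - d, n_to - k)
                - _log_comb(n_from, n_to))
    p = np.exp(logp)
    p[np.isnan(p)] = 0.0
    bad = (k > d) | ((n_to - k) > (n_from - d))
    p[bad] = 0.0
    return p


def fold_spectrum(xi: np.ndarray) -> np.ndarray:
    """Fold an unfolded spectrum of length n+1 to minor-allele classes.

    Returns an array of length floor(n/2)+1; bin 0 = monomorphic mass.
    """
    xi = np.asarray(xi, dtype=float)
    n = xi.size - 1
    half = n // 2
    eta = np.zeros(half + 1)
    for i in range(half + 1):
        if i == n - i:
            eta[i] = xi[i]
        else:
            eta[i] = xi[i] + xi[n - i]
    return eta


@dataclass
class FoldedSFS:
    """Folded spectrum: counts[i] = sites with minor-allele count i."""

    n: int
    counts: np.ndarray
    L: float | None = None

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("sample size must be >= 2")
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.size != self.n // 2 + 1:
            raise ValueError(f"counts must have length floor(n/2)+1 = {self.n // 2 + 1}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def segregating_sites(self) -> float:
        return float(self.counts[1:].sum())

    def __add__(self, other: "FoldedSFS") -> "FoldedSFS":
        if other.n != self.n:
            raise ValueError("cannot add spectra with different n")
        L = None
        if self.L is not None and other.L is not None:
            L = self.L + other.L
        return FoldedSFS(n=self.n, counts=self.counts + other.counts, L=L)

    def to_tsv(self, path) -> None:
        header = json.dumps({"n": self.n, "L": self.L, "folded": True})
        with open(path, "w") as fh:
            fh.write(f"#{header}\n")
            fh.write("minor_count\tsites\n")
            for i, c in enumerate(self.counts):
                fh.write(f"{i}\t{c:g}\n")

    @classmethod
    def from_tsv(cls, path) -> "FoldedSFS":
        with open(path) as fh:
            meta = json.loads(fh.readline().lstrip("#"))
            fh.readline()
            counts = [float(line.split("\t")[1]) for line in fh if line.strip()]
        return cls(n=meta["n"], counts=np.asarray(counts), L=meta.get("L"))


@dataclass
class FoldedJointSFS:
    """Folded 2-D spectrum over allele counts 0..n1 x 0..n2.

    ``mask`` marks invalid / folded-away cells; ``ambiguous`` marks the
    fold-diagonal cells whose mass was split evenly with the complement.
    """

    n1: int
    n2: int
    data: np.ndarray
    mask: np.ndarray
    ambiguous: np.ndarray = field(default=None)
    L: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (self.n1 + 1, self.n2 + 1):
            raise ValueError("data must be (n1+1) x (n2+1)")
        if self.mask is None:
            self.mask = default_joint_mask(self.n1, self.n2)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.ambiguous is None:
            self.ambiguous = np.zeros_like(self.mask)
        if np.any(self.data[self.mask] != 0):
            raise ValueError("masked cells must carry no counts")

    @property
    def total(self) -> float:
        return float(self.data[~self.mask].sum())

    def copy(self) -> "FoldedJointSFS":
        return FoldedJointSFS(n1=self.n1, n2=self.n2, data=self.data.copy(),
                              mask=self.mask.copy(),
                              ambiguous=self.ambiguous.copy(), L=self.L)

    def transposed(self) -> "FoldedJointSFS":
        return FoldedJointSFS(n1=self.n2, n2=self.n1, data=self.data.T.copy(),
                              mask=self.mask.T.copy(),
                              ambiguous=self.ambiguous.T.copy(), L=self.L)

    def to_tsv(self, path) -> None:
        header = json.dumps({"n1": self.n1, "n2": self.n2, "L": self.L,
                             "folded": True})
        with open(path, "w") as fh:
            fh.write(f"#{header}\n")
            for i in range(self.n1 + 1):
                fh.write("\t".join(
                    "masked" if self.mask[i, j] else f"{self.data[i, j]:.10g}"
                    for j in range(self.n2 + 1)) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "FoldedJointSFS":
        with open(path) as fh:
            meta = json.loads(fh.readline().lstrip("#"))
            rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
        n1, n2 = meta["n1"], meta["n2"]
        data = np.zeros((n1 + 1, n2 + 1))
        mask = np.zeros((n1 + 1, n2 + 1), dtype=bool)
        for i, row in enumerate(rows):
            for j, v in enumerate(row):
                if v == "masked":
                    mask[i, j] = True
                else:
                    data[i, j] = float(v)
        return cls(n1=n1, n2=n2, data=data, mask=mask, L=meta.get("L"))


def default_joint_mask(n1: int, n2: int) -> np.ndarray:
    """Mask for combined-minor folding: folded-away cells plus (0, 0)."""
    i = np.arange(n1 + 1)[:, None]
    j = np.arange(n2 + 1)[None, :]
    total = n1 + n2
    mask = (i + j) * 2 > total
    mask[0, 0] = True
    return mask


def fold_joint(unfolded: np.ndarray) -> FoldedJointSFS:
    """Fold an unfolded joint spectrum on the combined minor allele."""
    x = np.asarray(unfolded, dtype=float)
    n1, n2 = x.shape[0] - 1, x.shape[1] - 1
    total = n1 + n2
    data = np.zeros_like(x)
    ambiguous = np.zeros(x.shape, dtype=bool)
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            s = i + j
            ci, cj = n1 - i, n2 - j
            if 2 * s < total:
                data[i, j] = x[i, j] + x[ci, cj]
            elif 2 * s == total:
                data[i, j] = 0.5 * (x[i, j] + x[ci, cj])
                ambiguous[i, j] = True
    mask = default_joint_mask(n1, n2)
    data[mask] = 0.0
    ambiguous[mask] = False
    return FoldedJointSFS(n1=n1, n2=n2, data=data, mask=mask, ambiguous=ambiguous)


# ---------------------------------------------------------------------------
# Building spectra from genotypes


def _site_allele_counts(genotypes: np.ndarray):
    """Per-site (derived count, observed allele number) from diploid calls."""
    g = np.asarray(genotypes)
    called = g != MISSING
    n_obs = 2 * called.sum(axis=1)
    derived = np.where(called, g, 0).sum(axis=1)
    return derived.astype(np.int64), n_obs.astype(np.int64)


def unfolded_projected_counts(genotypes: np.ndarray, n: int) -> np.ndarray:
    """Accumulate per-site hypergeometric projections to sample size n.

    Returns a real-valued unfolded spectrum of length n+1.  Sites with
    fewer than n observed alleles are dropped.
    """
    derived, n_obs = _site_allele_counts(genotypes)
    xi = np.zeros(n + 1)
    for m in np.unique(n_obs):
        if m < n:
            continue
        sel = n_obs == m
        proj = projection_matrix(int(m), n)
        counts = np.bincount(derived[sel], minlength=int(m) + 1)
        xi += counts @ proj
    return xi


def build_folded_sfs(genotypes: np.ndarray, n: int,
                     site_mask: np.ndarray | None = None,
                     L: float | None = None) -> FoldedSFS:
    """Folded SFS at sample size ``n`` haploids from diploid genotypes."""
    if n < 2:
        raise ValueError("n must be >= 2")
    g = np.asarray(genotypes)
    if site_mask is not None:
        g = g[np.asarray(site_mask)]
    xi = unfolded_projected_counts(g, n)
    return FoldedSFS(n=n, counts=fold_spectrum(xi), L=L)


def build_folded_sfs_per_gene(genotypes: np.ndarray, gene_ids: np.ndarray,
                              n: int, site_mask: np.ndarray | None = None,
                              L: float | None = None) -> FoldedSFS:
    """Per-gene folded spectra summed into one class-level spectrum.

    Summing per-gene spectra equals pooling all sites directly; the
    grouping is retained for API parity with gene-based workflows.
    """
    g = np.asarray(genotypes)
    genes = np.asarray(gene_ids)
    if site_mask is not None:
        m = np.asarray(site_mask)
        g, genes = g[m], genes[m]
    total = FoldedSFS(n=n, counts=np.zeros(n // 2 + 1), L=L)
    for gene in np.unique(genes):
        total = total + build_folded_sfs(g[genes == gene], n)
    total.L = L
    return total


def project_sfs(sfs, n_target: int):
    """Hypergeometric down-projection of a spectrum.

    Accepts an unfolded array (length n+1; returns an array) or a
    :class:`FoldedSFS` (symmetrized, projected, refolded — the two
    operations commute in expectation).
    """
    if n_target < 2:
        raise ValueError("n_target must be >= 2")
    if isinstance(sfs, FoldedSFS):
        n = sfs.n
        if n_target > n:
            raise ValueError("cannot project upward")
        xi = np.zeros(n + 1)
        for i in range(sfs.counts.size):
            if i == n - i:
                xi[i] = sfs.counts[i]
            else:
                xi[i] = xi[n - i] = 0.5 * sfs.counts[i]
        proj = xi @ projection_matrix(n, n_target)
        return FoldedSFS(n=n_target, counts=fold_spectrum(proj), L=sfs.L)
    xi = np.asarray(sfs, dtype=float)
    n = xi.size - 1
    if n_target > n:
        raise ValueError("cannot project upward")
    return xi @ projection_matrix(n, n_target)


def build_joint_folded_sfs(genotypes_pop1: np.ndarray,
                           genotypes_pop2: np.ndarray,
                           n1_eff: int = 4, n2_eff: int = 4,
                           L: float | None = None) -> FoldedJointSFS:
    """Joint folded SFS with each population projected to n_eff chromosomes.

    With the default 4 and 4 the axes span allele counts 0..4.
    """
    g1 = np.asarray(genotypes_pop1)
    g2 = np.asarray(genotypes_pop2)
    if g1.shape[0] != g2.shape[0]:
        raise ValueError("population matrices must share sites")
    d1, m1 = _site_allele_counts(g1)
    d2, m2 = _site_allele_counts(g2)
    usable = (m1 >= n1_eff) & (m2 >= n2_eff)
    d1, m1, d2, m2 = d1[usable], m1[usable], d2[usable], m2[usable]

    unfolded = np.zeros((n1_eff + 1, n2_eff + 1))
    key = m1 * (2 * g2.shape[1] + 3) + m2
    for k in np.unique(key):
        sel = key == k
        mm1, mm2 = int(m1[sel][0]), int(m2[sel][0])
        W1 = projection_matrix(mm1, n1_eff)[d1[sel]]
        W2 = projection_matrix(mm2, n2_eff)[d2[sel]]
        unfolded += np.einsum("si,sj->ij", W1, W2)
    folded = fold_joint(unfolded)
    folded.L = L
    if folded.total == 0:
        warnings.warn("monomorphic-only input: empty joint spectrum")
    return folded


# ---------------------------------------------------------------------------
# Diversity statistics


def _tajima_constants(n: int):
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i ** 2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n ** 2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return a1, a2, e1, e2


def sfs_diversity(sfs: FoldedSFS, L: float):
    """(theta_W per site, pi per site, Tajima's D, S) from a folded SFS.

    D is ``nan`` when there are no segregating sites (undefined, not 0).
    """
    if L <= 0:
        raise ValueError("L must be positive")
    n = sfs.n
    a1, _, e1, e2 = _tajima_constants(n)
    S = sfs.segregating_sites
    i = np.arange(sfs.counts.size)
    pair_w = i * (n - i)
    pi_total = float(np.sum(pair_w * sfs.counts)) / (n * (n - 1) / 2.0)
    theta_w = S / a1 / L
    pi = pi_total / L
    if S <= 0:
        d = float("nan")
    else:
        d = (pi_total - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1.0))
    return theta_w, pi, d, S


@dataclass
class DiversitySummary:
    theta_w_syn: float
    pi_syn: float
    tajimas_d_syn: float
    S_syn: float
    theta_w_nonsyn: float
    pi_nonsyn: float
    tajimas_d_nonsyn: float
    S_nonsyn: float
    pi_n_pi_s: float


def diversity_summary(syn_sfs: FoldedSFS, nonsyn_sfs: FoldedSFS,
                      L_syn: float, L_nonsyn: float) -> DiversitySummary:
    """Per-class diversity statistics and the pi_N / pi_S ratio.

    The ratio uses per-site rates with the surveyed lengths from the
    annotation, so it is independent of site-count bookkeeping.
    """
    if syn_sfs.n != nonsyn_sfs.n:
        raise ValueError("spectra must share the sample size n")
    if L_syn <= 0 or L_nonsyn <= 0:
        raise ValueError("surveyed lengths must be positive")
    tw_s, pi_s, d_s, S_s = sfs_diversity(syn_sfs, L_syn)
    tw_n, pi_n, d_n, S_n = sfs_diversity(nonsyn_sfs, L_nonsyn)
    ratio = pi_n / pi_s if pi_s > 0 else float("nan")
    return DiversitySummary(theta_w_syn=tw_s, pi_syn=pi_s, tajimas_d_syn=d_s,
                            S_syn=S_s, theta_w_nonsyn=tw_n, pi_nonsyn=pi_n,
                            tajimas_d_nonsyn=d_n, S_nonsyn=S_n,
                            pi_n_pi_s=ratio)


def mean_pairwise_differences(genotypes: np.ndarray) -> float:
    """Direct mean pairwise difference count over all chromosome pairs,
    for complete-data cross-checks against the SFS-based pi."""
    g = np.asarray(genotypes)
    if np.any(g == MISSING):
        raise ValueError("direct pi requires complete data")
    n = 2 * g.shape[1]
    d = g.sum(axis=1)
    return float(np.sum(d * (n - d)) / (n * (n - 1) / 2.0))
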